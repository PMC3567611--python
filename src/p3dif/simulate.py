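"""Synthetic multi-participant P300 amplitude data with the generative structure
the hierarchical analysis assumes.

The generator mirrors the study design: one random stimulus sequence per
probability category (shared by all participants), N trials per block,
presented ``reps`` times with the trial-by-trial amplitude of repetition r

    Y_ℓ,r(n) = θ_ℓ + ϑ_ℓ · I(n) + ε,   ε ~ N(0, λ1),

averaged over repetitions, where I(n) is the generating observer model's
surprise (or expectancy) regressor and the participant parameters deviate
from the group values by N(0, λ2).  The returned per-participant trace
concatenates both categories (length 2N), exactly the shape the GLM fits.
Ground truth (every latent draw plus the regressor trace and its
fingerprint) is returned for recovery scoring.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import StimulusSequence, generate_sequence, write_sequence_csv, \
    read_sequence_csv
from .observers import DIFParams, SQUParams, model_trace, regressor
from .glm import HierarchicalFit, RegressorSet, build_design

__all__ = ["SimulationConfig", "SimDataset", "simulate_dataset",
           "recovery_score", "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults reproduce the design of the reference study — 16 participants,
    two probability categories ([0.5, 0.5] and [0.3, 0.7]) of 192 trials,
    six identical-sequence repetitions averaged — with the digital-filter
    observer at its published optimum as generator.  The group parameters
    (θ(2) = 3.5 μV, ϑ(2) = 1.0 μV/bit) and noise levels are configuration
    choices placing amplitudes in the empirically typical 2–5 μV range:
    λ1 = 25 μV² per-repetition trial noise (single-trial SD 5 μV, so the
    rep-averaged residual variance is ≈ 4.2 μV²) and λ2 = 1.0 for the
    participant scatter of both intercept and slope (the level-2 model
    shares one variance).
    """

    L: int = 16
    N: int = 192
    categories: tuple = ((0.5, 0.5), (0.3, 0.7))
    reps: int = 6
    model: str = "DIF"
    params: object = None              # DIFParams / SQUParams; None -> defaults
    theta2: float = 3.5                # group intercept, μV
    vartheta2: float = 1.0             # group slope, μV/bit
    lambda1: float = 25.0              # per-repetition trial noise variance
    lambda2: float = 1.0               # participant parameter scatter variance
    error_rate: float = 0.0            # probability a trial is dropped per rep
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("variances must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class SimDataset:
    """Sequences, rep-averaged amplitude traces, and the ground-truth record."""

    sequences: list              # one StimulusSequence per category
    Y: np.ndarray                # (L, 2N) rep-averaged amplitudes, μV
    truth: dict
    config: SimulationConfig

    @property
    def regressor_trace(self) -> np.ndarray:
        return self.truth["regressor"]


def _trace_fingerprint(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(x, dtype=float).tobytes()).hexdigest()


def _generator_params(config: SimulationConfig, category):
    if config.params is not None:
        return config.params
    if config.model == "DIF":
        return DIFParams()
    if config.model == "SQU":
        return SQUParams(P_k=tuple(category))
    return None  # MAR is parameter-free


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SimDataset:
    """Generate the full synthetic dataset, bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    seqs, reg_parts = [], []
    for cat in config.categories:
        seq_seed = int(rng.integers(0, 2 ** 31 - 1))
        seq = generate_sequence(len(cat), config.N, cat, seq_seed)
        seqs.append(seq)
        params = _generator_params(config, cat)
        trace = model_trace(config.model, seq, params)
        reg_parts.append(regressor(trace, seq))
    I = np.concatenate(reg_parts)                        # shared regressor, 2N
    n2 = I.size

    theta = config.theta2 + rng.normal(0.0, np.sqrt(config.lambda2), config.L)
    vartheta = config.vartheta2 + rng.normal(0.0, np.sqrt(config.lambda2), config.L)

    Y = np.empty((config.L, n2))
    for ell in range(config.L):
        signal = theta[ell] + vartheta[ell] * I
        reps = signal + rng.normal(0.0, np.sqrt(config.lambda1),
                                   size=(config.reps, n2))
        if config.error_rate > 0:
            keep = rng.random((config.reps, n2)) >= config.error_rate
            keep[0] = True                # never lose a trial entirely
            Y[ell] = (reps * keep).sum(axis=0) / keep.sum(axis=0)
        else:
            Y[ell] = reps.mean(axis=0)

    truth = {
        "theta2": config.theta2, "vartheta2": config.vartheta2,
        "lambda1": config.lambda1, "lambda2": config.lambda2,
        "theta": theta, "vartheta": vartheta,
        "regressor": I, "regressor_fingerprint": _trace_fingerprint(I),
        "sequence_seeds": [s.seed for s in seqs],
    }
    return SimDataset(sequences=seqs, Y=Y, truth=truth, config=config)


def design_from_dataset(ds: SimDataset) -> RegressorSet:
    """Design for fitting the *generating* model: reuses the exact regressor
    trace the data were built from (fingerprint-asserted, no recomputation
    drift)."""
    I = ds.truth["regressor"]
    if _trace_fingerprint(I) != ds.truth["regressor_fingerprint"]:
        raise AssertionError("regressor trace was modified since generation")
    return build_design([I] * ds.config.L, list(ds.Y))


def recovery_score(fit: HierarchicalFit, truth: dict, z: float = 1.959964) -> dict:
    """Bias and 95 % posterior-interval coverage of group and participant
    parameters against the generative ground truth."""
    g_true = np.array([truth["theta2"], truth["vartheta2"]])
    g_sd = fit.theta2_sd
    g_bias = fit.theta2_mean - g_true
    g_cover = np.abs(g_bias) <= z * g_sd

    p_true = np.column_stack([truth["theta"], truth["vartheta"]]).ravel()
    p_sd = np.sqrt(np.diag(fit.theta1_cov))
    p_bias = fit.theta1_mean - p_true
    p_cover = np.abs(p_bias) <= z * p_sd
    return {
        "group_bias": g_bias, "group_sd": g_sd,
        "group_covered": g_cover,
        "participant_bias_rms": float(np.sqrt(np.mean(p_bias ** 2))),
        "participant_coverage": float(np.mean(p_cover)),
    }


# --------------------------------------------------------------------------
# dataset bundle I/O
# --------------------------------------------------------------------------

def write_dataset(ds: SimDataset, outdir) -> None:
    """Write the bundle: sequence CSVs, amplitude CSV, truth JSON, config YAML."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, seq in enumerate(ds.sequences, start=1):
        write_sequence_csv(seq, outdir / f"sequence_cat{i}.csv")
    L, n2 = ds.Y.shape
    df = pd.DataFrame({
        "participant": np.repeat(np.arange(1, L + 1), n2),
        "trial": np.tile(np.arange(1, n2 + 1), L),
        "Y_uV": ds.Y.ravel(),
    })
    df.to_csv(outdir / "amplitudes.csv", index=False, float_format="%.17g")
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in ds.truth.items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    cfg = asdict(ds.config)
    cfg["params"] = None if ds.config.params is None else vars(ds.config.params) \
        if hasattr(ds.config.params, "__dict__") else asdict(ds.config.params)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))


def read_dataset(outdir) -> SimDataset:
    """Read a bundle written by :func:`write_dataset`."""
    import yaml

    outdir = Path(outdir)
    cfg = yaml.safe_load((outdir / "config.yaml").read_text())
    params = cfg.pop("params", None)
    cfg["categories"] = tuple(tuple(c) for c in cfg["categories"])
    if params is not None:
        params = DIFParams(**{k: v for k, v in params.items()}) \
            if cfg["model"] == "DIF" else SQUParams(**params)
    config = SimulationConfig(params=params, **cfg)
    seqs = [read_sequence_csv(outdir / f"sequence_cat{i}.csv")
            for i in range(1, len(config.categories) + 1)]
    df = pd.read_csv(outdir / "amplitudes.csv")
    L = df["participant"].max()
    Y = df.pivot(index="participant", columns="trial", values="Y_uV") \
        .sort_index().to_numpy()
    truth = json.loads((outdir / "truth.json").read_text())
    for k in ("theta", "vartheta", "regressor"):
        truth[k] = np.asarray(truth[k], dtype=float)
    return SimDataset(sequences=seqs, Y=Y, truth=truth, config=config)
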