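"""Synthetic data with planted ground truth.

Two generators back the recovery test-beds of the package:

* :func:`simulate_expression` builds a genes x samples TPM matrix over the
  four genotypes (WT, N1KO, N2KO, NDKO) with gene classes planted as log2
  fold-change triples, plus a truth table for recovery scoring.
* :func:`simulate_bioluminescence` builds a damped-cosine luminescence
  reporter trace on a regular sampling grid.

Planted effects are applied on the log2 scale before exponentiation, which
keeps fold changes exact and direction-symmetric. All randomness flows from
a single seed through per-stage child streams, so identical configs give
bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ExpressionStudy, GENOTYPES, MUTANTS

__all__ = [
    "PLANTED_CLASSES",
    "SimConfig",
    "BiolumSimConfig",
    "planted_effects",
    "allocate_class_counts",
    "simulate_expression",
    "simulate_bioluminescence",
]

#: Recognised planted gene classes. ``null`` genes carry no effect;
#: ``ndko_exclusive`` genes respond only to the double knockout;
#: ``additive`` genes split the double-knockout effect evenly between the
#: single mutants; ``alpha_dominant``/``beta_dominant`` genes respond to one
#: single mutant (NR1D1 resp. NR1D2) and to the double knockout.
PLANTED_CLASSES = (
    "null",
    "ndko_exclusive_up",
    "ndko_exclusive_down",
    "additive_up",
    "additive_down",
    "alpha_dominant_up",
    "alpha_dominant_down",
    "beta_dominant_up",
    "beta_dominant_down",
)

_DEFAULT_FRACTIONS = {
    "null": 0.70,
    "ndko_exclusive_up": 0.05,
    "ndko_exclusive_down": 0.05,
    "additive_up": 0.03,
    "additive_down": 0.03,
    "alpha_dominant_up": 0.035,
    "alpha_dominant_down": 0.035,
    "beta_dominant_up": 0.035,
    "beta_dominant_down": 0.035,
}


def planted_effects(label: str, delta: float) -> tuple[float, float, float]:
    """Log2 fold-change triple (delta_N1, delta_N2, delta_ND) for a class.

    ``delta`` is the planted effect magnitude in log2 units and applies to
    the double knockout; additive classes give each single mutant half of it.
    """
    sign = -1.0 if label.endswith("_down") else 1.0
    base = label.rsplit("_", 1)[0] if label != "null" else "null"
    if label == "null":
        return (0.0, 0.0, 0.0)
    if base == "ndko_exclusive":
        return (0.0, 0.0, sign * delta)
    if base == "additive":
        return (sign * delta / 2, sign * delta / 2, sign * delta)
    if base == "alpha_dominant":
        return (sign * delta, 0.0, sign * delta)
    if base == "beta_dominant":
        return (0.0, sign * delta, sign * delta)
    raise ValueError(f"unknown planted class {label!r}")


@dataclass
class SimConfig:
    """Configuration for the planted-class TPM simulator.

    Defaults mirror the four-replicate, four-genotype design the pipeline
    targets: n_replicates=4 per genotype, replicate noise 0.15 on the log2
    scale, and a planted double-knockout effect of log2(3) (a 3-fold change).
    """

    n_genes: int = 2000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    replicate_sd: float = 0.15
    n_replicates: int = 4
    delta: float = math.log2(3.0)
    seed: int = 0
    tpm_rescale: bool = False

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        unknown = set(self.class_fractions) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")


def allocate_class_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` genes to classes.

    Each class gets floor(fraction * n); the leftover genes go to the
    classes with the largest fractional remainders, ties broken by the
    insertion order of ``fractions``. Deterministic by construction.
    """
    quotas = {k: f * n for k, f in fractions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    order = sorted(
        fractions,
        key=lambda k: (-(quotas[k] - counts[k]), list(fractions).index(k)),
    )
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def simulate_expression(config: SimConfig) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate a TPM matrix with planted gene classes.

    Per gene g and sample s of genotype G, log2 TPM is drawn as
    Normal(baseline_g + delta_G(class_g), replicate_sd^2) with delta_WT = 0,
    then exponentiated. With ``tpm_rescale`` every sample column is scaled
    to sum to 1e6 (true TPM semantics) at the cost of perturbing planted
    fold changes slightly.

    Returns the study and a truth table (gene, label, delta_n1, delta_n2,
    delta_nd), one row per simulated gene, classes assigned to gene indices
    in allocation order.
    """
    config.validate()
    counts = allocate_class_counts(config.class_fractions, config.n_genes)
    for label, frac in config.class_fractions.items():
        if frac > 0 and counts[label] == 0:
            warnings.warn(
                f"class {label!r} (fraction {frac}) received 0 genes and is dropped",
                stacklevel=2,
            )

    labels: list[str] = []
    for label in config.class_fractions:
        labels.extend([label] * counts[label])
    effects = np.array([planted_effects(lb, config.delta) for lb in labels])

    width = max(5, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(config.n_genes)]

    ss = np.random.SeedSequence(config.seed)
    baseline_ss, noise_ss = ss.spawn(2)
    baseline = np.random.default_rng(baseline_ss).normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )

    samples = [
        f"{g}_{r}" for g in GENOTYPES for r in range(1, config.n_replicates + 1)
    ]
    # delta per genotype column: WT=0, mutants from the planted triple
    delta_by_geno = {"WT": np.zeros(config.n_genes)}
    for j, g in enumerate(MUTANTS):
        delta_by_geno[g] = effects[:, j]

    rng = np.random.default_rng(noise_ss)
    log2tpm = np.empty((config.n_genes, len(samples)))
    for j, s in enumerate(samples):
        geno = s.rsplit("_", 1)[0]
        noise = (
            rng.normal(0.0, config.replicate_sd, config.n_genes)
            if config.replicate_sd > 0
            else 0.0
        )
        log2tpm[:, j] = baseline + delta_by_geno[geno] + noise

    tpm = np.exp2(log2tpm)
    if config.tpm_rescale:
        tpm = tpm * (1e6 / tpm.sum(axis=0, keepdims=True))

    matrix = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"), columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "genotype": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    ).set_index("sample")
    truth = pd.DataFrame(
        {
            "gene": genes,
            "label": labels,
            "delta_n1": effects[:, 0],
            "delta_n2": effects[:, 1],
            "delta_nd": effects[:, 2],
        }
    ).set_index("gene")
    return ExpressionStudy(matrix, design), truth


@dataclass
class BiolumSimConfig:
    """Damped-cosine bioluminescence trace parameters.

    The default grid (96 h at 20-min intervals) matches a multi-day
    luminometer recording of dexamethasone-synchronised reporter cells.
    ``damping_rate`` is the exponential decay constant of the oscillation
    envelope in 1/h; ``acrophase`` is the peak time in hours.
    """

    mesor: float = 100.0
    trend_slope: float = 0.0
    amplitude: float = 20.0
    damping_rate: float = 0.0
    period: float = 24.0
    acrophase: float = 6.0
    noise_sd: float = 0.0
    duration: float = 96.0
    sampling_interval: float = 1.0 / 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")


def simulate_bioluminescence(config: BiolumSimConfig) -> pd.DataFrame:
    """Simulate y(t) = M + b*t + A*exp(-lambda*t)*cos(2*pi*(t-phi)/tau) + noise.

    The grid runs from t=0 to ``duration`` inclusive at ``sampling_interval``
    spacing. Returns a two-column frame (time_h, signal); seed-reproducible.
    """
    config.validate()
    n = int(round(config.duration / config.sampling_interval))
    t = np.arange(n + 1) * config.sampling_interval
    envelope = config.amplitude * np.exp(-config.damping_rate * t)
    y = (
        config.mesor
        + config.trend_slope * t
        + envelope * np.cos(2 * np.pi * (t - config.acrophase) / config.period)
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        y = y + rng.normal(0.0, config.noise_sd, t.shape)
    return pd.DataFrame({"time_h": t, "signal": y})
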