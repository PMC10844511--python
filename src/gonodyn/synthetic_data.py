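"""Synthetic two-sex, two-stage expression datasets with planted truth.

Generates counts (negative-binomial with sample-specific library sizes) or
log2 intensities (Gaussian) for a 2 sexes x 2 stages design.  Genes are
planted as male- or female-enriched via three mechanisms (upregulation in
the own sex only, downregulation in the opposite sex only, or both),
shared-direction up/down, or null, and the exact per-gene effects are
returned alongside the dataset for recovery testing.

All randomness flows from one generator seeded by the config, with draws in
a fixed documented order: gene baselines, effect magnitudes, class
assignment permutation, library sizes, then the expression noise.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gonodyn.dynamics import (
    CLASS_FEG,
    CLASS_MEG,
    CLASS_SHARED,
    MECH_BOTH,
    MECH_NA,
    MECH_OPP_DOWN,
    MECH_OWN_UP,
    MechanismSummary,
)
from gonodyn.exceptions import ValidationError
from gonodyn.io import ExpressionDataset

PROPORTION_KEYS = (
    "meg_up",        # MEG via upregulation in males only
    "meg_down_opp",  # MEG via downregulation in females only
    "meg_both",      # MEG via both
    "feg_up",
    "feg_down_opp",
    "feg_both",
    "shared_up",
    "shared_down",
    "null",
)

_CLASS_OF_KEY = {
    "meg_up": (CLASS_MEG, MECH_OWN_UP),
    "meg_down_opp": (CLASS_MEG, MECH_OPP_DOWN),
    "meg_both": (CLASS_MEG, MECH_BOTH),
    "feg_up": (CLASS_FEG, MECH_OWN_UP),
    "feg_down_opp": (CLASS_FEG, MECH_OPP_DOWN),
    "feg_both": (CLASS_FEG, MECH_BOTH),
    "shared_up": (CLASS_SHARED, MECH_NA),
    "shared_down": (CLASS_SHARED, MECH_NA),
    "null": ("NULL", MECH_NA),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``proportions`` maps the nine planted categories (see PROPORTION_KEYS)
    to fractions summing to 1.  Count baselines are log-normal in log2 space
    with per-gene dispersion alpha_g = dispersion + dispersion_a0 / mu_g;
    intensity baselines are Gaussian log2 values with residual noise.
    """

    n_genes: int = 10_000
    replicates: int = 3
    platform: str = "counts"
    proportions: dict[str, float] = field(
        default_factory=lambda: {"null": 1.0}
    )
    effect_low: float = 2.0
    effect_high: float = 4.0
    # counts platform
    log2_mean_loc: float = 6.0
    log2_mean_scale: float = 1.5
    dispersion: float = 0.05
    dispersion_a0: float = 0.0
    lib_size_low: float = 0.7
    lib_size_high: float = 1.4
    # intensity platform
    intensity_mean: float = 8.0
    intensity_sd: float = 2.0
    residual_sd: float = 0.25
    seed: int = 0
    species_label: str = "sim"

    def __post_init__(self) -> None:
        if self.platform not in ("counts", "intensity"):
            raise ValidationError(f"platform must be counts/intensity, got {self.platform!r}")
        if self.replicates < 2:
            raise ValidationError("replicates per (sex, stage) cell must be >=2")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >=1")
        unknown = set(self.proportions) - set(PROPORTION_KEYS)
        if unknown:
            raise ValidationError(f"unknown proportion keys: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        if self.effect_low <= 0:
            raise ValidationError("effect_low must be > 0")
        if self.effect_high < self.effect_low:
            raise ValidationError("effect_high must be >= effect_low")
        if not (0 < self.lib_size_low <= self.lib_size_high):
            raise ValidationError("library size range must satisfy 0 < low <= high")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def largest_remainder_counts(proportions: Sequence[float], total: int) -> np.ndarray:
    """Integer counts per category: floor(p*total) plus largest remainders.

    Remaining units after flooring go to the categories with the largest
    fractional parts (earlier category wins ties), so category counts equal
    round(p*total) up to the forced +-1 reconciliation and sum exactly to
    ``total``.
    """
    props = np.asarray(proportions, dtype=float)
    exact = props * total
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = exact - counts
        order = np.argsort(-frac, kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _planted_deltas(
    keys: np.ndarray, mag1: np.ndarray, mag2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (delta_f, delta_m) from category keys and drawn magnitudes.

    Shared genes get equal deltas in both sexes; 'both'-mechanism genes get
    independent magnitudes for the up and the down component.
    """
    delta_f = np.zeros(len(keys))
    delta_m = np.zeros(len(keys))
    sel = keys == "meg_up"
    delta_m[sel] = mag1[sel]
    sel = keys == "meg_down_opp"
    delta_f[sel] = -mag1[sel]
    sel = keys == "meg_both"
    delta_m[sel] = mag1[sel]
    delta_f[sel] = -mag2[sel]
    sel = keys == "feg_up"
    delta_f[sel] = mag1[sel]
    sel = keys == "feg_down_opp"
    delta_m[sel] = -mag1[sel]
    sel = keys == "feg_both"
    delta_f[sel] = mag1[sel]
    delta_m[sel] = -mag2[sel]
    sel = keys == "shared_up"
    delta_f[sel] = mag1[sel]
    delta_m[sel] = mag1[sel]
    sel = keys == "shared_down"
    delta_f[sel] = -mag1[sel]
    delta_m[sel] = -mag1[sel]
    return delta_f, delta_m


def _sample_layout(replicates: int) -> pd.DataFrame:
    rows = []
    for sex in ("F", "M"):
        for stage in ("T1", "T2"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{sex}_{stage}_{rep}",
                        "sex": sex,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one dataset and its planted truth table.

    The truth table is indexed by gene id with columns ``class``,
    ``mechanism``, ``delta_f`` and ``delta_m`` (the planted per-sex T1->T2
    log2 fold changes).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    samples = _sample_layout(config.replicates)
    n_samples = len(samples)

    # 1. gene baselines
    if config.platform == "counts":
        mu = np.exp2(rng.normal(config.log2_mean_loc, config.log2_mean_scale, n))
        baseline = None
    else:
        baseline = rng.normal(config.intensity_mean, config.intensity_sd, n)
        mu = None

    # 2. effect magnitudes (two streams so 'both' genes decouple up and down)
    mag1 = rng.uniform(config.effect_low, config.effect_high, n)
    mag2 = rng.uniform(config.effect_low, config.effect_high, n)

    # 3. category assignment via largest-remainder counts + permutation
    props = [config.proportions.get(k, 0.0) for k in PROPORTION_KEYS]
    counts_per_key = largest_remainder_counts(props, n)
    keys = np.repeat(np.array(PROPORTION_KEYS, dtype=object), counts_per_key)
    keys = keys[rng.permutation(n)]

    delta_f, delta_m = _planted_deltas(keys, mag1, mag2)

    # planted change happens between T1 and T2: T1 means are sex-balanced
    delta_by_sample = np.zeros((n, n_samples))
    for j, (sid, row) in enumerate(samples.iterrows()):
        if row["stage"] == "T2":
            delta_by_sample[:, j] = delta_f if row["sex"] == "F" else delta_m

    # 4. library sizes (counts only), then 5. expression noise
    if config.platform == "counts":
        lib = np.exp(
            rng.uniform(
                math.log(config.lib_size_low),
                math.log(config.lib_size_high),
                n_samples,
            )
        )
        mean_matrix = lib[None, :] * mu[:, None] * np.exp2(delta_by_sample)
        alpha = config.dispersion + config.dispersion_a0 / mu
        alpha = np.maximum(alpha, 0.0)
        values = np.empty((n, n_samples), dtype=np.int64)
        poisson_like = alpha < 1e-12
        if poisson_like.any():
            values[poisson_like] = rng.poisson(mean_matrix[poisson_like])
        nb = ~poisson_like
        if nb.any():
            shape = 1.0 / alpha[nb]
            lam = rng.gamma(
                shape[:, None], mean_matrix[nb] * alpha[nb][:, None]
            )
            values[nb] = rng.poisson(lam)
        matrix = pd.DataFrame(values, index=gene_ids, columns=samples.index)
    else:
        noise = rng.normal(0.0, config.residual_sd, (n, n_samples))
        matrix = pd.DataFrame(
            baseline[:, None] + delta_by_sample + noise,
            index=gene_ids,
            columns=samples.index,
        )

    truth = pd.DataFrame(
        {
            "class": [_CLASS_OF_KEY[k][0] for k in keys],
            "mechanism": [_CLASS_OF_KEY[k][1] for k in keys],
            "delta_f": delta_f,
            "delta_m": delta_m,
        },
        index=gene_ids,
    )
    dataset = ExpressionDataset(
        values=matrix,
        samples=samples,
        platform=config.platform,
        species_label=config.species_label,
    )
    return dataset, truth


def planted_summary(truth: pd.DataFrame) -> MechanismSummary:
    """Truth-side mechanism summary, mirroring the estimated one."""
    if len(truth) == 0:
        raise ValidationError("empty truth table")
    cls = truth["class"]
    mech = truth["mechanism"]
    meg = cls == CLASS_MEG
    feg = cls == CLASS_FEG
    return MechanismSummary(
        males_up=int((meg & mech.isin([MECH_OWN_UP, MECH_BOTH])).sum()),
        females_down=int((meg & (mech == MECH_OPP_DOWN)).sum()),
        females_up=int((feg & mech.isin([MECH_OWN_UP, MECH_BOTH])).sum()),
        males_down=int((feg & (mech == MECH_OPP_DOWN)).sum()),
        both_sexes=int((cls == CLASS_SHARED).sum()),
        total_degs=int((cls != "NULL").sum()),
        total_genes=len(truth),
    )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    # "NULL" and "n/a" are labels, not missing values
    truth = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    truth["delta_f"] = truth["delta_f"].astype(float)
    truth["delta_m"] = truth["delta_m"].astype(float)
    truth.index = truth.index.astype(str)
    return truth
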