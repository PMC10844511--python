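"""Fold-change-plane gene dynamics: classification and summaries.

Each gene's two within-sex stage fold changes form a point (FC_female on X,
FC_male on Y).  Genes significant in at least one sex are classified as
male-enriched (MEG), female-enriched (FEG) or shared-direction (SHARED)
using the between-sex contrast at the later stage, and MEG/FEG genes get a
mechanism label describing how enrichment arose: upregulation in the own
sex only, downregulation in the opposite sex only, or both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gonodyn import de_engine
from gonodyn.de_engine import DEResult
from gonodyn.exceptions import ValidationError
from gonodyn.io import ExpressionDataset

logger = logging.getLogger(__name__)

CLASS_MEG = "MEG"
CLASS_FEG = "FEG"
CLASS_SHARED = "SHARED"
CLASS_NONSIG = "NONSIG"

MECH_OWN_UP = "own-up-only"
MECH_OPP_DOWN = "opposite-down-only"
MECH_BOTH = "both"
MECH_NA = "n/a"


@dataclass
class MechanismSummary:
    """Per-species counts of DEGs by enrichment mechanism.

    ``males_up``    - MEGs upregulated in males (own-up-only or both)
    ``females_down``- MEGs enriched solely through downregulation in females
    ``females_up``  - FEGs upregulated in females (own-up-only or both)
    ``males_down``  - FEGs enriched solely through downregulation in males
    ``both_sexes``  - genes changed in the same direction in both sexes

    The five categories are disjoint and partition ``total_degs``.
    """

    males_up: int
    males_down: int
    females_up: int
    females_down: int
    both_sexes: int
    total_degs: int
    total_genes: int

    def __post_init__(self) -> None:
        cat_sum = (
            self.males_up
            + self.males_down
            + self.females_up
            + self.females_down
            + self.both_sexes
        )
        if cat_sum != self.total_degs:
            raise ValidationError(
                f"mechanism categories sum to {cat_sum}, not total_degs={self.total_degs}"
            )
        if self.total_degs > self.total_genes:
            raise ValidationError("total_degs exceeds total_genes")

    @classmethod
    def from_category_counts(
        cls,
        males_up: int,
        males_down: int,
        females_up: int,
        females_down: int,
        both_sexes: int,
        total_genes: int | None = None,
    ) -> "MechanismSummary":
        """Aggregate the five category counts into a summary (total = sum)."""
        total = males_up + males_down + females_up + females_down + both_sexes
        return cls(
            males_up=males_up,
            males_down=males_down,
            females_up=females_up,
            females_down=females_down,
            both_sexes=both_sexes,
            total_degs=total,
            total_genes=total if total_genes is None else total_genes,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "males_up": self.males_up,
            "males_down": self.males_down,
            "females_up": self.females_up,
            "females_down": self.females_down,
            "both_sexes": self.both_sexes,
            "total_degs": self.total_degs,
            "total_genes": self.total_genes,
        }

    def write(self, path) -> None:
        pd.DataFrame([self.as_dict()]).to_csv(path, sep="\t", index=False)


def between_sex_contrast_t2(
    dataset: ExpressionDataset,
    stage: str = "T2",
    **options,
) -> DEResult:
    """M-vs-F contrast at the later stage, with the same engine and thresholds.

    log2FC is male relative to female: positive = male-enriched.
    """
    cols_f = dataset.sample_ids(sex="F", stage=stage)
    cols_m = dataset.sample_ids(sex="M", stage=stage)
    if len(cols_f) < 2 or len(cols_m) < 2:
        raise ValidationError(
            f"between-sex contrast at {stage} needs >=2 samples per sex "
            f"(F: {len(cols_f)}, M: {len(cols_m)})"
        )
    deg_opts = {
        k: options.pop(k)
        for k in ("fc_threshold", "alpha", "fc_scale")
        if k in options
    }
    if dataset.platform == "intensity":
        allowed = {"prior_df"}
        opts = {k: v for k, v in options.items() if k in allowed}
        table = de_engine.moderated_t_core(dataset.values, cols_f, cols_m, **opts)
    else:
        table = de_engine.nb_wald_core(dataset.values, cols_f, cols_m, **options)
    result = DEResult(
        table=table, contrast=("F", "M"), sex=None, platform=dataset.platform
    )
    return de_engine.apply_deg_filter(result, **deg_opts)


def classify_gene(
    fc_female: float,
    fc_male: float,
    sig_female: bool,
    sig_male: bool,
    t2_log2fc: float,
    t2_sig: bool,
    rule: str = "t2_test",
    margin: float = de_engine.DEFAULT_FC_THRESHOLD,
) -> tuple[str, str]:
    """Classify one gene and assign its enrichment mechanism.

    With ``rule='t2_test'`` a gene significant in >=1 sex is MEG/FEG when the
    between-sex contrast at T2 is significant (sign gives the sex), SHARED
    otherwise.  ``rule='fc_margin'`` instead compares fc_male - fc_female to
    ``margin`` without an extra test.
    """
    if (sig_female and not np.isfinite(fc_female)) or (
        sig_male and not np.isfinite(fc_male)
    ):
        raise ValidationError("significant gene with missing fold change")
    if not (sig_female or sig_male):
        return CLASS_NONSIG, MECH_NA

    if rule == "t2_test":
        if t2_sig and t2_log2fc > 0:
            cls = CLASS_MEG
        elif t2_sig and t2_log2fc < 0:
            cls = CLASS_FEG
        else:
            cls = CLASS_SHARED
    elif rule == "fc_margin":
        diff = (fc_male if np.isfinite(fc_male) else 0.0) - (
            fc_female if np.isfinite(fc_female) else 0.0
        )
        if diff >= margin:
            cls = CLASS_MEG
        elif diff <= -margin:
            cls = CLASS_FEG
        else:
            cls = CLASS_SHARED
    else:
        raise ValidationError(f"unknown classification rule: {rule!r}")

    if cls == CLASS_MEG:
        own_up = sig_male and fc_male > 0
        opp_down = sig_female and fc_female < 0
    elif cls == CLASS_FEG:
        own_up = sig_female and fc_female > 0
        opp_down = sig_male and fc_male < 0
    else:
        return cls, MECH_NA

    if own_up and opp_down:
        return cls, MECH_BOTH
    if own_up:
        return cls, MECH_OWN_UP
    if opp_down:
        return cls, MECH_OPP_DOWN
    # significant change inconsistent with the enrichment direction
    # (e.g. only a same-direction change in the non-enriched sex): treat as
    # shared-direction rather than invent a mechanism
    return CLASS_SHARED, MECH_NA


def build_dynamics_table(
    de_female: DEResult,
    de_male: DEResult,
    t2_contrast: DEResult,
    rule: str = "t2_test",
    margin: float = de_engine.DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Combine per-sex results and the T2 contrast into classified points.

    Keeps genes present in all three inputs with padj computed in at least
    one sex; drops the rest with a logged count.
    """
    idx = de_female.table.index.intersection(de_male.table.index).intersection(
        t2_contrast.table.index
    )
    if len(idx) == 0:
        raise ValidationError("gene universes of the three results are disjoint")
    n_dropped_universe = (
        len(de_female.table.index.union(de_male.table.index).union(t2_contrast.table.index))
        - len(idx)
    )

    tf = de_female.table.loc[idx]
    tm = de_male.table.loc[idx]
    tc = t2_contrast.table.loc[idx]

    has_padj = tf["padj"].notna() | tm["padj"].notna()
    n_dropped_padj = int((~has_padj).sum())
    idx = idx[has_padj]
    tf, tm, tc = tf.loc[idx], tm.loc[idx], tc.loc[idx]
    if n_dropped_universe or n_dropped_padj:
        logger.info(
            "dynamics table: dropped %d genes missing from an input and %d "
            "with no adjusted p-value in either sex",
            n_dropped_universe,
            n_dropped_padj,
        )
    if len(idx) == 0:
        raise ValidationError("no genes with an adjusted p-value in either sex")

    points = pd.DataFrame(
        {
            "fc_female": tf["log2fc"],
            "fc_male": tm["log2fc"],
            "sig_female": tf["is_deg"].astype(bool),
            "sig_male": tm["is_deg"].astype(bool),
            "t2_log2fc": tc["log2fc"],
            "t2_padj": tc["padj"],
            "t2_sig": tc["is_deg"].astype(bool),
            "min_padj": pd.concat([tf["padj"], tm["padj"]], axis=1).min(axis=1),
            "base_mean": pd.concat(
                [tf["base_mean"], tm["base_mean"]], axis=1
            ).mean(axis=1),
        },
        index=idx,
    )
    classes = []
    mechanisms = []
    for row in points.itertuples():
        cls, mech = classify_gene(
            row.fc_female,
            row.fc_male,
            row.sig_female,
            row.sig_male,
            row.t2_log2fc,
            row.t2_sig,
            rule=rule,
            margin=margin,
        )
        classes.append(cls)
        mechanisms.append(mech)
    points["class"] = classes
    points["mechanism"] = mechanisms
    return points.rename_axis("gene_id")


def summarize_mechanisms(points: pd.DataFrame, total_genes: int) -> MechanismSummary:
    """Count classified points into the five disjoint mechanism categories."""
    cls = points["class"]
    mech = points["mechanism"]
    meg = cls == CLASS_MEG
    feg = cls == CLASS_FEG
    males_up = int((meg & mech.isin([MECH_OWN_UP, MECH_BOTH])).sum())
    females_down = int((meg & (mech == MECH_OPP_DOWN)).sum())
    females_up = int((feg & mech.isin([MECH_OWN_UP, MECH_BOTH])).sum())
    males_down = int((feg & (mech == MECH_OPP_DOWN)).sum())
    both_sexes = int((cls == CLASS_SHARED).sum())
    total_degs = int((cls != CLASS_NONSIG).sum())
    return MechanismSummary(
        males_up=males_up,
        males_down=males_down,
        females_up=females_up,
        females_down=females_down,
        both_sexes=both_sexes,
        total_degs=total_degs,
        total_genes=int(total_genes),
    )


def mechanism_percentages(summary: MechanismSummary) -> dict[str, float]:
    """Share of MEGs (resp. FEGs) enriched via up- vs downregulation.

    MEG-up% = males_up / (males_up + females_down); MEG-down% is its
    complement via the females_down count.  FEG analogously with females_up
    and males_down.  Zero denominators give NaN.
    """
    meg_total = summary.males_up + summary.females_down
    feg_total = summary.females_up + summary.males_down
    nan = float("nan")
    return {
        "meg_up_pct": 100.0 * summary.males_up / meg_total if meg_total else nan,
        "meg_down_pct": 100.0 * summary.females_down / meg_total if meg_total else nan,
        "feg_up_pct": 100.0 * summary.females_up / feg_total if feg_total else nan,
        "feg_down_pct": 100.0 * summary.males_down / feg_total if feg_total else nan,
    }


def write_dynamics_table(points: pd.DataFrame, path) -> None:
    points.to_csv(path, sep="\t")


def read_dynamics_table(path) -> pd.DataFrame:
    points = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=True)
    points.index = points.index.astype(str)
    for col in ("sig_female", "sig_male", "t2_sig"):
        points[col] = points[col].astype(bool)
    # class/mechanism labels such as "n/a" must survive the round trip
    points["class"] = points["class"].fillna("NONSIG")
    points["mechanism"] = points["mechanism"].fillna("n/a").replace({"nan": "n/a"})
    return points
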