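"""Cross-species comparison: symbol harmonization, key-gene panel report,
fold-change variability statistics, and top-gene marker discovery."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gonodyn.dynamics import CLASS_FEG, CLASS_MEG, CLASS_NONSIG
from gonodyn.exceptions import ValidationError
from gonodyn.io import OrthologMap

logger = logging.getLogger(__name__)

#: canonical six-gene panel: first three male-associated, last three female-associated
DEFAULT_PANEL = ("AMH", "SOX9", "DMRT1", "CYP19A1", "FOXL2", "FST")
DEFAULT_MEG_PANEL = DEFAULT_PANEL[:3]
DEFAULT_FEG_PANEL = DEFAULT_PANEL[3:]

_FIELDS = (
    "fc_female",
    "fc_male",
    "sig_female",
    "sig_male",
    "class",
    "min_padj",
)


@dataclass
class AlignedFCTable:
    """Canonical-symbol x species grid of per-sex fold changes and classes.

    ``data`` has a (species, field) column MultiIndex and one row per
    canonical symbol; cells are NaN where a species lacks the gene.
    """

    data: pd.DataFrame
    species: list[str] = field(default_factory=list)
    unmapped_counts: dict[str, int] = field(default_factory=dict)

    def get(self, species: str) -> pd.DataFrame:
        sub = self.data[species].dropna(how="all")
        return sub


def _collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """One row per canonical symbol: keep the most informative probe.

    Preference: the probe with the largest max(|fc|) over its significant
    per-sex changes; if no probe is significant, the one with the largest
    base mean (falling back to largest max(|fc|)).
    """
    sig_fc = pd.DataFrame(
        {
            "f": table["fc_female"].where(table["sig_female"]),
            "m": table["fc_male"].where(table["sig_male"]),
        }
    ).abs()
    sig_rank = sig_fc.max(axis=1)
    if "base_mean" in table.columns:
        fallback = table["base_mean"]
    else:
        fallback = table[["fc_female", "fc_male"]].abs().max(axis=1)
    # significant probes always outrank non-significant ones
    score = np.where(sig_rank.notna(), 1e9 + sig_rank.fillna(0), fallback)
    order = np.argsort(-score, kind="stable")
    deduped = table.iloc[order]
    return deduped[~deduped["symbol"].duplicated()]


def harmonize_symbols(
    dynamics_tables: dict[str, pd.DataFrame],
    ortholog_map: OrthologMap | None = None,
) -> AlignedFCTable:
    """Map native ids to canonical symbols and align species side by side.

    Unmapped ids are retained uppercased (count logged per species); probes
    sharing a symbol within one species are collapsed to the most
    informative probe.
    """
    if not dynamics_tables:
        raise ValidationError("no species tables to harmonize")
    species = list(dynamics_tables)
    blocks = {}
    unmapped_counts: dict[str, int] = {}
    for sp in species:
        table = dynamics_tables[sp].copy()
        natives = table.index.astype(str)
        if ortholog_map is not None:
            symbols = [ortholog_map.canonicalize(sp, g) for g in natives]
            unmapped = sum(
                1 for g in natives if ortholog_map.lookup(sp, g) is None
            )
        else:
            symbols = [g.strip().upper() for g in natives]
            unmapped = len(natives)
        unmapped_counts[sp] = unmapped
        if ortholog_map is not None and unmapped:
            logger.info("%s: %d ids without ortholog-map entry (kept uppercased)", sp, unmapped)
        table["symbol"] = symbols
        table = _collapse_probes(table)
        if table["symbol"].duplicated().any():
            dups = table.loc[table["symbol"].duplicated(), "symbol"].unique()
            raise ValidationError(
                f"{sp}: symbols still duplicated after probe collapse: {list(dups[:5])}"
            )
        block = table.set_index("symbol")[list(_FIELDS)]
        blocks[sp] = block
    data = pd.concat(blocks, axis=1)  # columns: (species, field)
    data.index.name = "symbol"
    return AlignedFCTable(data=data, species=species, unmapped_counts=unmapped_counts)


def _species_significant(aligned: AlignedFCTable, symbol: str, sp: str) -> bool:
    block = aligned.data
    if (sp, "sig_female") not in block.columns or symbol not in block.index:
        return False
    row = block.loc[symbol, sp]

    def _truthy(v) -> bool:
        return pd.notna(v) and bool(v)

    return _truthy(row.get("sig_female")) or _truthy(row.get("sig_male"))


def key_gene_panel(
    aligned: AlignedFCTable,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    min_species: int = 3,
) -> pd.DataFrame:
    """Per panel-gene, per-species grid of fold changes and classes.

    A gene is ``reportable`` when significant (DEG in >=1 sex) in at least
    ``min_species`` species.  Missing species cells are NaN.
    """
    if not panel:
        raise ValidationError("empty key-gene panel")
    rows = []
    for symbol in panel:
        symbol = symbol.upper()
        n_sig = 0
        n_present = 0
        for sp in aligned.species:
            present = symbol in aligned.data.index and not pd.isna(
                aligned.data.loc[symbol, (sp, "class")]
            )
            if present:
                n_present += 1
                if _species_significant(aligned, symbol, sp):
                    n_sig += 1
            rows.append(
                {
                    "gene": symbol,
                    "species": sp,
                    "fc_female": aligned.data.loc[symbol, (sp, "fc_female")]
                    if present
                    else np.nan,
                    "fc_male": aligned.data.loc[symbol, (sp, "fc_male")]
                    if present
                    else np.nan,
                    "class": aligned.data.loc[symbol, (sp, "class")]
                    if present
                    else np.nan,
                    "significant": _species_significant(aligned, symbol, sp)
                    if present
                    else False,
                }
            )
        for row in rows[-len(aligned.species):]:
            row["n_species_significant"] = n_sig
            row["n_species_present"] = n_present
            row["reportable"] = n_sig >= min_species
    return pd.DataFrame(rows)


def panel_fc_stats(
    aligned: AlignedFCTable, panel: tuple[str, ...] = DEFAULT_PANEL
) -> pd.DataFrame:
    """Mean and sample SD of per-sex fold changes across species per gene.

    NA-skipping; a gene/sex with fewer than two non-NA species gets NaN SD
    (single value: mean kept) with a logged warning.
    """
    records = []
    for symbol in panel:
        symbol = symbol.upper()
        rec: dict[str, float | str] = {"gene": symbol}
        for sex, col in (("female", "fc_female"), ("male", "fc_male")):
            vals = []
            for sp in aligned.species:
                if symbol in aligned.data.index:
                    v = aligned.data.loc[symbol, (sp, col)]
                    if pd.notna(v):
                        vals.append(float(v))
            if len(vals) == 0:
                rec[f"mean_{sex}"] = np.nan
                rec[f"sd_{sex}"] = np.nan
            else:
                rec[f"mean_{sex}"] = float(np.mean(vals))
                rec[f"sd_{sex}"] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
            if len(vals) < 2:
                logger.warning("%s/%s: <2 species with estimates; SD is NA", symbol, sex)
            rec[f"n_{sex}"] = len(vals)
        records.append(rec)
    return pd.DataFrame(records).set_index("gene")


def sd_sex_difference_test(
    aligned: AlignedFCTable,
    genes: tuple[str, ...],
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of the sex difference of cross-species FC variability.

    Statistic: mean over the given genes of SD(fc_male across species) minus
    mean of SD(fc_female).  The null swaps each gene-by-species (fc_m, fc_f)
    pair's sex labels independently; two-sided p with the +1 correction.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    pairs: list[np.ndarray] = []  # per gene: (n_species, 2) array [f, m]
    for symbol in genes:
        symbol = symbol.upper()
        fs, ms = [], []
        for sp in aligned.species:
            if symbol in aligned.data.index:
                f = aligned.data.loc[symbol, (sp, "fc_female")]
                m = aligned.data.loc[symbol, (sp, "fc_male")]
                if pd.notna(f) and pd.notna(m):
                    fs.append(float(f))
                    ms.append(float(m))
        if len(fs) < 2:
            raise ValidationError(f"{symbol}: <2 species with both-sex estimates")
        pairs.append(np.column_stack([fs, ms]))

    def statistic(mats: list[np.ndarray]) -> float:
        sd_f = [np.std(m[:, 0], ddof=1) for m in mats]
        sd_m = [np.std(m[:, 1], ddof=1) for m in mats]
        return float(np.mean(sd_m) - np.mean(sd_f))

    observed = statistic(pairs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        permuted = []
        for mat in pairs:
            flips = rng.random(mat.shape[0]) < 0.5
            pm = mat.copy()
            pm[flips] = pm[flips][:, ::-1]
            permuted.append(pm)
        if abs(statistic(permuted)) >= abs(observed):
            count += 1
    pvalue = (1 + count) / (n_perm + 1)
    return {"statistic": observed, "pvalue": pvalue, "n_perm": n_perm}


def top_genes(dynamics_table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Top fraction of DEGs by largest absolute significant fold change.

    The universe is DEGs (significant in >=1 sex); the rank key is the max
    |FC| over the gene's significant per-sex changes, ties broken by smaller
    min padj then lexicographic id.  List size = ceil(fraction * nDEG).
    """
    degs = dynamics_table[dynamics_table["class"] != CLASS_NONSIG].copy()
    if len(degs) == 0:
        return degs.assign(rank_fc=pd.Series(dtype=float))
    rank_fc = pd.DataFrame(
        {
            "f": degs["fc_female"].where(degs["sig_female"]),
            "m": degs["fc_male"].where(degs["sig_male"]),
        }
    ).abs().max(axis=1)
    degs["rank_fc"] = rank_fc.fillna(0.0)
    size = math.ceil(fraction * len(degs))
    degs["_gene"] = degs.index.astype(str)
    degs = degs.sort_values(
        by=["rank_fc", "min_padj", "_gene"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_gene")
    return degs.head(size)


def shared_top_genes(
    per_species_lists: dict[str, "pd.Index | list[str] | set[str]"],
    min_species: int = 3,
) -> set[str]:
    """Symbols appearing in the top lists of at least ``min_species`` species."""
    if len(per_species_lists) < min_species:
        raise ValidationError(
            f"{len(per_species_lists)} species lists but min_species={min_species}"
        )
    counts: dict[str, int] = {}
    for symbols in per_species_lists.values():
        for s in set(str(x).upper() for x in symbols):
            counts[s] = counts.get(s, 0) + 1
    return {s for s, c in counts.items() if c >= min_species}


def novel_markers(shared_set: set[str], key_panel: tuple[str, ...] = DEFAULT_PANEL) -> set[str]:
    """Shared top genes outside the key panel."""
    panel = {p.upper() for p in key_panel}
    return {s.upper() for s in shared_set} - panel
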