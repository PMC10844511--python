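"""Gene-set overrepresentation of FEGs and MEGs and conserved-pathway calls.

Uses the exact upper-tail hypergeometric probability with a dataset-specific
background and, by design, no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gonodyn.exceptions import ValidationError
from gonodyn.io import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05


@dataclass
class EnrichmentRecord:
    set_id: str
    query_size: int
    background_size: int
    set_size: int
    overlap: int
    gene_ratio: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "query_size": self.query_size,
            "background_size": self.background_size,
            "set_size": self.set_size,
            "overlap": self.overlap,
            "gene_ratio": self.gene_ratio,
            "pvalue": self.pvalue,
        }


def overrepresentation_test(
    query_genes, background_genes, gene_set: GeneSet
) -> EnrichmentRecord:
    """Exact hypergeometric upper-tail test of a query list against one set.

    p = P(X >= overlap) with population = |background|, successes =
    |set intersect background| and draws = |query|.  The query must be a
    subset of the background.
    """
    query = {str(g).upper() for g in query_genes}
    background = {str(g).upper() for g in background_genes}
    outside = query - background
    if outside:
        raise ValidationError(
            f"query genes absent from background: {sorted(outside)[:5]}"
        )
    members = gene_set.members & background
    overlap = len(query & members)
    M, n, N = len(background), len(members), len(query)
    if overlap == 0:
        pvalue = 1.0
    else:
        pvalue = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    gene_ratio = overlap / N if N else 0.0
    return EnrichmentRecord(
        set_id=gene_set.set_id,
        query_size=N,
        background_size=M,
        set_size=n,
        overlap=overlap,
        gene_ratio=gene_ratio,
        pvalue=min(max(pvalue, 0.0), 1.0),
    )


def _enrich_one(
    query, background, collection: GeneSetCollection, p_threshold: float
) -> pd.DataFrame:
    background = {str(g).upper() for g in background}
    records = []
    for gs in collection:
        if not (gs.members & background):
            logger.warning("set %s disjoint from background; skipped", gs.set_id)
            continue
        rec = overrepresentation_test(query, background, gs)
        records.append(rec.as_dict())
    table = pd.DataFrame(
        records,
        columns=[
            "set_id",
            "query_size",
            "background_size",
            "set_size",
            "overlap",
            "gene_ratio",
            "pvalue",
        ],
    )
    table["enriched"] = table["pvalue"] < p_threshold
    return table.sort_values(["pvalue", "set_id"], kind="stable").reset_index(drop=True)


def enrich_all(
    feg_genes,
    meg_genes,
    background_genes,
    collection: GeneSetCollection,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overrepresentation tables for the FEG and MEG query lists.

    One record per gene set per query, sorted by p; ``enriched`` flags
    uncorrected p below ``p_threshold``.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    feg_table = _enrich_one(feg_genes, background_genes, collection, p_threshold)
    meg_table = _enrich_one(meg_genes, background_genes, collection, p_threshold)
    return feg_table, meg_table


def conserved_pathways(
    per_species_tables: dict[str, dict[str, pd.DataFrame]],
    min_species: int = 3,
) -> pd.DataFrame:
    """Pathways enriched on one side (FEG/MEG) in at least ``min_species`` species.

    ``per_species_tables`` maps species label to {'FEG': table, 'MEG': table}
    as returned by ``enrich_all``.  Output rows carry the side label
    (FEG-only / MEG-only / both) and per-species gene ratios for plotting.
    """
    n_species = len(per_species_tables)
    if min_species > n_species:
        raise ValidationError(
            f"min_species={min_species} exceeds species count {n_species}"
        )
    counts: dict[str, dict[str, int]] = {}
    ratios: dict[tuple[str, str, str], float] = {}
    for sp, sides in per_species_tables.items():
        for side in ("FEG", "MEG"):
            table = sides[side]
            for row in table.itertuples():
                counts.setdefault(row.set_id, {"FEG": 0, "MEG": 0})
                if row.enriched:
                    counts[row.set_id][side] += 1
                ratios[(row.set_id, side, sp)] = row.gene_ratio

    records = []
    species = list(per_species_tables)
    for set_id, c in sorted(counts.items()):
        feg_ok = c["FEG"] >= min_species
        meg_ok = c["MEG"] >= min_species
        if not (feg_ok or meg_ok):
            continue
        label = "both" if (feg_ok and meg_ok) else ("FEG-only" if feg_ok else "MEG-only")
        rec = {
            "set_id": set_id,
            "label": label,
            "n_species_feg": c["FEG"],
            "n_species_meg": c["MEG"],
        }
        for sp in species:
            rec[f"feg_ratio_{sp}"] = ratios.get((set_id, "FEG", sp), np.nan)
            rec[f"meg_ratio_{sp}"] = ratios.get((set_id, "MEG", sp), np.nan)
        records.append(rec)
    return pd.DataFrame(records)
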