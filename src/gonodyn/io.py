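"""Readers, writers and validation for the pipeline's external formats.

Handles gene/probe-by-sample expression matrices with a sample sheet
(sex in {F, M}, stage in {T1, T2}), GMT gene-set collections and
species/alias ortholog maps.  Intensity matrices are assumed to hold
already-normalized log2 values; no normalization is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from gonodyn.exceptions import ValidationError

SEXES = ("F", "M")
STAGES = ("T1", "T2")
PLATFORMS = ("counts", "intensity")

_SEX_TOKENS = {
    "F": "F",
    "FEMALE": "F",
    "FEM": "F",
    "M": "M",
    "MALE": "M",
}
_STAGE_TOKENS = {
    "T1": "T1",
    "T2": "T2",
    "1": "T1",
    "2": "T2",
    "STAGE1": "T1",
    "STAGE2": "T2",
}


def normalize_sex(token: str) -> str:
    key = str(token).strip().upper()
    if key not in _SEX_TOKENS:
        raise ValidationError(f"unrecognized sex token: {token!r}")
    return _SEX_TOKENS[key]


def normalize_stage(token: str) -> str:
    key = str(token).strip().upper()
    if key not in _STAGE_TOKENS:
        raise ValidationError(f"unrecognized stage token: {token!r}")
    return _STAGE_TOKENS[key]


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with its experimental design.

    ``values`` is indexed by gene (probe) id with one column per sample;
    ``samples`` is indexed by sample id with columns ``sex``, ``stage`` and
    ``replicate`` and is aligned to the matrix columns in order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str
    species_label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"platform must be one of {PLATFORMS}, got {self.platform!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError(
                "sample ids of the matrix and the sample sheet do not match "
                f"(matrix: {list(self.values.columns)[:5]}..., "
                f"sheet: {list(self.samples.index)[:5]}...)"
            )
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")

        vals = self.values.to_numpy()
        if self.platform == "counts":
            if (vals < 0).any():
                raise ValidationError("negative value in counts matrix")
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("non-integer count in counts matrix")

        sexes = set(self.samples["sex"])
        stages = set(self.samples["stage"])
        if sexes != set(SEXES):
            raise ValidationError(f"expected both sexes {SEXES}, found {sorted(sexes)}")
        if stages != set(STAGES):
            raise ValidationError(
                f"expected both stages {STAGES}, found {sorted(stages)}"
            )
        cell_sizes = self.samples.groupby(["sex", "stage"], observed=True).size()
        for (sex, stage), n in cell_sizes.items():
            if n < 2:
                raise ValidationError(
                    f"design cell ({sex}, {stage}) has {n} sample(s); >=2 required"
                )

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, sex: str | None = None, stage: str | None = None) -> list[str]:
        """Sample ids matching the given sex and/or stage, in matrix order."""
        mask = pd.Series(True, index=self.samples.index)
        if sex is not None:
            mask &= self.samples["sex"] == normalize_sex(sex)
        if stage is not None:
            mask &= self.samples["stage"] == normalize_stage(stage)
        return list(self.samples.index[mask])


def _sniff_sep(path: str | Path) -> str:
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet with columns sample_id, sex, stage [, replicate]."""
    sep = _sniff_sep(path)
    sheet = pd.read_csv(path, sep=sep, dtype=str)
    sheet.columns = [c.strip().lower() for c in sheet.columns]
    required = {"sample_id", "sex", "stage"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    sheet["sex"] = sheet["sex"].map(normalize_sex)
    sheet["stage"] = sheet["stage"].map(normalize_stage)
    sheet = sheet.set_index("sample_id")
    if "replicate" in sheet.columns:
        sheet["replicate"] = sheet["replicate"].astype(int)
    else:
        sheet["replicate"] = sheet.groupby(["sex", "stage"], observed=True).cumcount() + 1
    return sheet[["sex", "stage", "replicate"]]


def read_expression_dataset(
    matrix_path: str | Path,
    samples_path: str | Path,
    platform: str,
    species_label: str = "",
) -> ExpressionDataset:
    """Read and validate a delimited expression matrix plus its sample sheet.

    The first matrix column holds gene ids; remaining columns are samples.
    Matrix column order is preserved; the sheet is reordered to match it.
    """
    sep = _sniff_sep(matrix_path)
    matrix = pd.read_csv(matrix_path, sep=sep, index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = [str(c) for c in matrix.columns]
    sheet = read_sample_sheet(samples_path)

    matrix_ids = set(matrix.columns)
    sheet_ids = set(sheet.index)
    if matrix_ids != sheet_ids:
        only_m = sorted(matrix_ids - sheet_ids)[:5]
        only_s = sorted(sheet_ids - matrix_ids)[:5]
        raise ValidationError(
            f"sample id mismatch between matrix and sheet "
            f"(matrix only: {only_m}, sheet only: {only_s})"
        )
    sheet = sheet.loc[list(matrix.columns)]
    if platform == "counts":
        # reject 3.5-style values before the cast truncates them
        vals = matrix.to_numpy(dtype=float)
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("non-integer count in counts matrix")
        matrix = matrix.astype(np.int64)
    return ExpressionDataset(
        values=matrix, samples=sheet, platform=platform, species_label=species_label
    )


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write a dataset back to TSV (matrix + sample sheet), round-trip safe."""
    dataset.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    dataset.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member symbols."""
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return frozenset(out)


def read_gene_sets(gmt_path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: set_id TAB description TAB member...

    Member symbols are uppercased; duplicates within a line are dropped.
    """
    collection = GeneSetCollection()
    with open(gmt_path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{gmt_path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, description, *members = fields
            if set_id in collection:
                raise ValidationError(f"{gmt_path}:{lineno}: duplicate set id {set_id!r}")
            symbols = frozenset(m.strip().upper() for m in members if m.strip())
            if not symbols:
                raise ValidationError(f"{gmt_path}:{lineno}: set {set_id!r} has no members")
            collection.sets[set_id] = GeneSet(set_id, description, symbols)
    return collection


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "wt", encoding="utf-8") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# ortholog / alias map
# ---------------------------------------------------------------------------


@dataclass
class OrthologMap:
    """Mapping from (species, native symbol) to a canonical uppercase symbol.

    Rows with species ``*`` are global aliases applying to every species.
    Native symbols match case-insensitively.
    """

    species_map: dict[tuple[str, str], str] = field(default_factory=dict)
    global_map: dict[str, str] = field(default_factory=dict)

    def add(self, species: str, native: str, canonical: str) -> None:
        canonical = canonical.strip().upper()
        native_key = native.strip().upper()
        if species == "*":
            existing = self.global_map.get(native_key)
            if existing is not None and existing != canonical:
                raise ValidationError(
                    f"conflicting global alias for {native!r}: "
                    f"{existing!r} vs {canonical!r}"
                )
            self.global_map[native_key] = canonical
        else:
            key = (species, native_key)
            existing = self.species_map.get(key)
            if existing is not None and existing != canonical:
                raise ValidationError(
                    f"conflicting mapping for ({species}, {native!r}): "
                    f"{existing!r} vs {canonical!r}"
                )
            self.species_map[key] = canonical

    def lookup(self, species: str, native: str) -> str | None:
        """Canonical symbol for a native id, or None if unmapped."""
        native_key = native.strip().upper()
        hit = self.species_map.get((species, native_key))
        if hit is not None:
            return hit
        return self.global_map.get(native_key)

    def canonicalize(self, species: str, native: str) -> str:
        """Mapped canonical symbol, falling back to the uppercased native id."""
        hit = self.lookup(species, native)
        return hit if hit is not None else native.strip().upper()


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a 3-column map: species (or ``*``), native_symbol, canonical_symbol."""
    sep = _sniff_sep(path)
    table = pd.read_csv(path, sep=sep, dtype=str)
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"species", "native_symbol", "canonical_symbol"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"ortholog map missing columns: {sorted(missing)}")
    omap = OrthologMap()
    for row in table.itertuples(index=False):
        omap.add(str(row.species), str(row.native_symbol), str(row.canonical_symbol))
    return omap
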