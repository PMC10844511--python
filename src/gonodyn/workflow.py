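"""Pipeline orchestration: per-species analysis and cross-species comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from gonodyn import cross_species, de_engine, dynamics, enrichment, synthetic_data
from gonodyn.cross_species import DEFAULT_PANEL, AlignedFCTable
from gonodyn.de_engine import DEResult
from gonodyn.dynamics import MechanismSummary
from gonodyn.exceptions import ValidationError
from gonodyn.io import (
    ExpressionDataset,
    GeneSetCollection,
    OrthologMap,
    read_expression_dataset,
    read_gene_sets,
    read_ortholog_map,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    fc_threshold: float = de_engine.DEFAULT_FC_THRESHOLD
    fc_scale: str = "log2"
    alpha: float = de_engine.DEFAULT_ALPHA
    cooks_cutoff: float = de_engine.DEFAULT_COOKS_CUTOFF
    if_alpha: float = de_engine.DEFAULT_IF_ALPHA
    min_total_count: int = de_engine.DEFAULT_MIN_TOTAL_COUNT
    classification_rule: str = "t2_test"

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "alpha", "cooks_cutoff", "if_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")

    def engine_options(self, platform: str) -> dict:
        opts = {
            "fc_threshold": self.fc_threshold,
            "fc_scale": self.fc_scale,
            "alpha": self.alpha,
        }
        if platform == "counts":
            opts.update(
                cooks_cutoff=self.cooks_cutoff,
                if_alpha=self.if_alpha,
                min_total_count=self.min_total_count,
            )
        return opts


@dataclass
class SpeciesSpec:
    label: str
    platform: str = "counts"
    matrix: str | None = None
    samples: str | None = None
    simulate: dict | None = None


@dataclass
class PipelineConfig:
    species: list[SpeciesSpec] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    panel: tuple[str, ...] = DEFAULT_PANEL
    top_fraction: float = 0.10
    min_species: int = 3
    n_perm: int = 999
    enrichment_p: float = enrichment.DEFAULT_P_THRESHOLD
    gene_sets: str | None = None
    ortholog_map: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        species = [SpeciesSpec(**entry) for entry in raw.get("species", [])]
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            species=species,
            thresholds=thresholds,
            panel=tuple(raw.get("panel", DEFAULT_PANEL)),
            top_fraction=float(raw.get("top_fraction", 0.10)),
            min_species=int(raw.get("min_species", 3)),
            n_perm=int(raw.get("n_perm", 999)),
            enrichment_p=float(raw.get("enrichment_p", enrichment.DEFAULT_P_THRESHOLD)),
            gene_sets=raw.get("gene_sets"),
            ortholog_map=raw.get("ortholog_map"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class SpeciesResult:
    label: str
    de_female: DEResult
    de_male: DEResult
    t2_contrast: DEResult
    dynamics_table: pd.DataFrame
    summary: MechanismSummary
    top: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.de_female.write(outdir / f"{self.label}.de_female.tsv")
        self.de_male.write(outdir / f"{self.label}.de_male.tsv")
        self.t2_contrast.write(outdir / f"{self.label}.t2_contrast.tsv")
        dynamics.write_dynamics_table(
            self.dynamics_table, outdir / f"{self.label}.dynamics.tsv"
        )
        self.summary.write(outdir / f"{self.label}.summary.tsv")
        self.top.to_csv(outdir / f"{self.label}.top_genes.tsv", sep="\t")


def load_species_dataset(
    spec: SpeciesSpec, base_seed: int = 0, index: int = 0
) -> tuple[ExpressionDataset, pd.DataFrame | None]:
    """Materialize one species' dataset from files or a simulation block."""
    if spec.simulate is not None:
        sim_opts = dict(spec.simulate)
        sim_opts.setdefault("platform", spec.platform)
        sim_opts.setdefault("seed", base_seed + index)
        sim_opts.setdefault("species_label", spec.label)
        config = synthetic_data.SimulationConfig.from_dict(sim_opts)
        return synthetic_data.simulate_dataset(config)
    if spec.matrix is None or spec.samples is None:
        raise ValidationError(
            f"species {spec.label}: either matrix+samples paths or a simulate block required"
        )
    dataset = read_expression_dataset(
        spec.matrix, spec.samples, spec.platform, species_label=spec.label
    )
    return dataset, None


def run_species(
    dataset: ExpressionDataset,
    thresholds: Thresholds | None = None,
    top_fraction: float = 0.10,
    outdir: str | Path | None = None,
) -> SpeciesResult:
    """Per-species pipeline: per-sex DE, T2 contrast, dynamics, summary, top genes."""
    thresholds = thresholds or Thresholds()
    opts = thresholds.engine_options(dataset.platform)
    logger.info("%s: %d genes, %d samples (%s)", dataset.species_label,
                dataset.n_genes, dataset.n_samples, dataset.platform)
    de_female = de_engine.run_stage_contrast(dataset, sex="F", **opts)
    logger.info("%s: female contrast, %d DEGs", dataset.species_label, de_female.n_deg)
    de_male = de_engine.run_stage_contrast(dataset, sex="M", **opts)
    logger.info("%s: male contrast, %d DEGs", dataset.species_label, de_male.n_deg)
    t2 = dynamics.between_sex_contrast_t2(dataset, **opts)
    logger.info("%s: T2 between-sex contrast, %d DEGs", dataset.species_label, t2.n_deg)
    points = dynamics.build_dynamics_table(
        de_female, de_male, t2, rule=thresholds.classification_rule
    )
    summary = dynamics.summarize_mechanisms(points, total_genes=dataset.n_genes)
    logger.info(
        "%s: %d DEGs of %d genes (males up/down %d/%d, females up/down %d/%d, both %d)",
        dataset.species_label, summary.total_degs, summary.total_genes,
        summary.males_up, summary.males_down, summary.females_up,
        summary.females_down, summary.both_sexes,
    )
    top = cross_species.top_genes(points, fraction=top_fraction)
    result = SpeciesResult(
        label=dataset.species_label or "species",
        de_female=de_female,
        de_male=de_male,
        t2_contrast=t2,
        dynamics_table=points,
        summary=summary,
        top=top,
    )
    if outdir is not None:
        result.write(outdir)
    return result


@dataclass
class ComparisonResult:
    aligned: AlignedFCTable
    panel_report: pd.DataFrame
    panel_stats: pd.DataFrame
    sd_tests: dict[str, dict[str, float]]
    shared_top: set[str]
    novel: set[str]
    enrichment_tables: dict[str, dict[str, pd.DataFrame]]
    conserved: pd.DataFrame | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.aligned.data.to_csv(outdir / "aligned_fc.tsv", sep="\t")
        self.panel_report.to_csv(outdir / "panel_report.tsv", sep="\t", index=False)
        self.panel_stats.to_csv(outdir / "panel_stats.tsv", sep="\t")
        pd.DataFrame(self.sd_tests).T.rename_axis("group").to_csv(
            outdir / "sd_sex_difference.tsv", sep="\t"
        )
        pd.Series(sorted(self.shared_top), name="symbol").to_csv(
            outdir / "shared_top_genes.tsv", sep="\t", index=False
        )
        pd.Series(sorted(self.novel), name="symbol").to_csv(
            outdir / "novel_markers.tsv", sep="\t", index=False
        )
        for sp, sides in self.enrichment_tables.items():
            for side, table in sides.items():
                table.to_csv(outdir / f"{sp}.enrichment_{side.lower()}.tsv", sep="\t", index=False)
        if self.conserved is not None:
            self.conserved.to_csv(outdir / "conserved_pathways.tsv", sep="\t", index=False)


def run_comparison(
    species_results: dict[str, SpeciesResult],
    config: PipelineConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    ortholog_map: OrthologMap | None = None,
    outdir: str | Path | None = None,
) -> ComparisonResult:
    """Cross-species stages: harmonize, panel, SD tests, shared/novel markers,
    per-species enrichment and conserved pathways."""
    if len(species_results) < 2:
        raise ValidationError("comparison requires >=2 species")
    config = config or PipelineConfig()
    if gene_sets is None and config.gene_sets:
        gene_sets = read_gene_sets(config.gene_sets)
    if ortholog_map is None and config.ortholog_map:
        ortholog_map = read_ortholog_map(config.ortholog_map)

    tables = {sp: res.dynamics_table for sp, res in species_results.items()}
    aligned = cross_species.harmonize_symbols(tables, ortholog_map)
    panel_report = cross_species.key_gene_panel(
        aligned, panel=config.panel, min_species=config.min_species
    )
    panel_stats = cross_species.panel_fc_stats(aligned, panel=config.panel)

    half = max(len(config.panel) // 2, 1)
    meg_panel = tuple(config.panel[:half])
    feg_panel = tuple(config.panel[half:])
    sd_tests = {}
    for name, genes in (("MEG-panel", meg_panel), ("FEG-panel", feg_panel)):
        try:
            sd_tests[name] = cross_species.sd_sex_difference_test(
                aligned, genes, n_perm=config.n_perm, seed=config.seed
            )
        except ValidationError as exc:
            logger.warning("SD test for %s skipped: %s", name, exc)

    # top lists on the canonical-symbol scale
    top_lists = {}
    for sp, res in species_results.items():
        if ortholog_map is not None:
            symbols = [ortholog_map.canonicalize(sp, g) for g in res.top.index]
        else:
            symbols = [str(g).upper() for g in res.top.index]
        top_lists[sp] = symbols
    shared = cross_species.shared_top_genes(top_lists, min_species=config.min_species)
    novel = cross_species.novel_markers(shared, key_panel=config.panel)
    logger.info("shared top genes: %d, novel markers: %d", len(shared), len(novel))

    enrichment_tables: dict[str, dict[str, pd.DataFrame]] = {}
    conserved = None
    if gene_sets is not None:
        from gonodyn.dynamics import CLASS_FEG, CLASS_MEG

        universe = gene_sets.universe
        for sp, res in species_results.items():
            block = aligned.get(sp)
            annotated = block.index.isin(universe)
            background = set(block.index[annotated])
            feg = [
                s
                for s in block.index[(block["class"] == CLASS_FEG) & annotated]
            ]
            meg = [
                s
                for s in block.index[(block["class"] == CLASS_MEG) & annotated]
            ]
            if not background:
                logger.warning("%s: no annotated genes; enrichment skipped", sp)
                continue
            feg_t, meg_t = enrichment.enrich_all(
                feg, meg, background, gene_sets, p_threshold=config.enrichment_p
            )
            enrichment_tables[sp] = {"FEG": feg_t, "MEG": meg_t}
        if enrichment_tables:
            conserved = enrichment.conserved_pathways(
                enrichment_tables, min_species=min(config.min_species, len(enrichment_tables))
            )

    result = ComparisonResult(
        aligned=aligned,
        panel_report=panel_report,
        panel_stats=panel_stats,
        sd_tests=sd_tests,
        shared_top=shared,
        novel=novel,
        enrichment_tables=enrichment_tables,
        conserved=conserved,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    plots: bool = False,
) -> tuple[dict[str, SpeciesResult], ComparisonResult | None]:
    """Full pipeline over every configured species plus the comparison."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_results: dict[str, SpeciesResult] = {}
    for i, spec in enumerate(config.species):
        dataset, truth = load_species_dataset(spec, base_seed=config.seed, index=i)
        if truth is not None:
            synthetic_data.write_truth(truth, outdir / f"{spec.label}.truth.tsv")
        species_results[spec.label] = run_species(
            dataset,
            thresholds=config.thresholds,
            top_fraction=config.top_fraction,
            outdir=outdir,
        )
    comparison = None
    if len(species_results) >= 2:
        comparison = run_comparison(species_results, config=config, outdir=outdir)
    if plots:
        from gonodyn import plots as _plots

        for sp, res in species_results.items():
            _plots.fc_plane_scatter(
                res.dynamics_table, outdir / f"{sp}.fc_plane.png", title=sp
            )
        _plots.mechanism_bars(
            {sp: res.summary for sp, res in species_results.items()},
            outdir / "mechanism_bars.png",
        )
        if comparison is not None:
            _plots.panel_scatter(comparison.panel_report, outdir / "panel_scatter.png")
            if comparison.conserved is not None and len(comparison.conserved):
                _plots.enrichment_bars(
                    comparison.conserved, outdir / "conserved_pathways.png"
                )
    return species_results, comparison
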