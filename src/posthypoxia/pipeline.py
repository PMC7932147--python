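"""End-to-end orchestration of the posthypoxic profiling analysis.

``run_pipeline`` assembles the full report from either synthetic data (with
known ground truth) or user-supplied tables: duplicate averaging and
control-bead normalization, the exact permutation screen per tissue, the
cross-tissue Venn partition of primary hits, sample clustering with
group-segregation scores, and the OCT / histology group statistics.  The
bundle is deterministic for a fixed configuration and every written table
carries the configuration fingerprint that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .cluster import ClusterResult, hier_cluster, segregation_score
from .panel import DEFAULT_PANEL, AnalytePanel
from .preprocess import NormalizedMatrix, average_duplicates, chex_normalize
from .screen import ImmuneScreenResults, run_screen, venn_partition
from .simulate import (
    SimConfig,
    simulate_histology,
    simulate_luminex_plate,
    simulate_oct_table,
)
from .structstats import (
    RetinalThicknessStudy,
    anova_tukey,
    group_summary,
    two_way_anova,
)

__all__ = ["RunConfig", "PipelineBundle", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of simulation (``simulate=True``) or explicit input paths
    must be active.  ``seed`` overrides the simulation seed so one flag
    controls all randomness.
    """

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    plasma_path: str | None = None
    retina_path: str | None = None
    oct_path: str | None = None
    histology_path: str | None = None
    averaged_inputs: bool = False

    group: str = "post1h"
    statistic: str = "mean_diff"
    sided: str = "two"
    q: float = 0.1
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"

    panel: AnalytePanel = field(default_factory=lambda: DEFAULT_PANEL)
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = any([self.plasma_path, self.retina_path, self.oct_path,
                          self.histology_path])
        if self.simulate and has_inputs:
            raise ValueError("exactly one of simulation or input paths may be active")
        if not self.simulate and not has_inputs:
            raise ValueError("either simulate=True or at least one input path is required")
        if self.simulate and self.sim.seed != self.seed:
            object.__setattr__(self, "sim", SimConfig(**{
                **self.sim.__dict__, "seed": self.seed,
            }))

    def fingerprint(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineBundle:
    """In-memory results of a full pipeline run."""

    config: RunConfig
    matrices: dict[str, NormalizedMatrix]
    screens: dict[str, ImmuneScreenResults]
    venn: tuple[set[str], set[str], set[str]] | None
    clusters: dict[str, ClusterResult]
    segregation: dict[str, float]
    oct_results: object | None
    histology_summary: pd.DataFrame | None
    tunel_anova: pd.DataFrame | None

    def write(self, outdir: str | Path) -> Path:
        """Write all bundle tables under ``outdir`` (TSV + plain text)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            fp = self.config.fingerprint()
            for tissue, screen in self.screens.items():
                path = out / f"screen_{tissue}.tsv"
                pio.write_screen_results(screen.results, path)
                written.append(path)
            for tissue, matrix in self.matrices.items():
                path = out / f"matrix_{tissue}.tsv"
                pio.write_matrix(matrix.values, matrix.meta, path)
                written.append(path)
            for tissue, cres in self.clusters.items():
                path = out / f"dendrogram_{tissue}.nwk"
                path.write_text(cres.to_newick() + "\n")
                written.append(path)
                path = out / f"leaf_order_{tissue}.tsv"
                pd.Series(cres.leaf_order, name="sample").to_csv(
                    path, sep="\t", index=False
                )
                written.append(path)
            if self.oct_results is not None:
                path = out / "oct_report.tsv"
                self.oct_results.layer_table.to_csv(path, sep="\t", index=False)
                written.append(path)
            if self.histology_summary is not None:
                path = out / "histology_report.tsv"
                self.histology_summary.to_csv(path, sep="\t", index=False)
                written.append(path)
            if self.tunel_anova is not None:
                path = out / "tunel_anova.tsv"
                self.tunel_anova.to_csv(path, sep="\t")
                written.append(path)
            path = out / "run_summary.txt"
            path.write_text(self.summary() + "\n")
            written.append(path)
            meta = out / "run_config.json"
            meta.write_text(json.dumps(
                {"fingerprint": fp, "seed": self.config.seed,
                 "simulate": self.config.simulate,
                 "statistic": self.config.statistic,
                 "sided": self.config.sided, "q": self.config.q},
                indent=2, sort_keys=True,
            ) + "\n")
            written.append(meta)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        return out

    def summary(self) -> str:
        lines = [
            f"configuration fingerprint: {self.config.fingerprint()}",
            f"seed: {self.config.seed}",
            "",
        ]
        for tissue, screen in self.screens.items():
            lines.append(f"== {tissue} ==")
            lines.append(screen.summary())
            if tissue in self.segregation:
                lines.append(
                    f"segregation score ({self.config.group}): "
                    f"{self.segregation[tissue]:.3f}"
                )
            lines.append("")
        if self.venn is not None:
            only_a, shared, only_b = self.venn
            lines.append(
                f"Venn of primary hits (plasma | shared | retina): "
                f"{sorted(only_a)} | {sorted(shared)} | {sorted(only_b)}"
            )
            lines.append("")
        if self.oct_results is not None:
            lines.append("== OCT thickness ==")
            lines.append(self.oct_results.summary())
            lines.append("")
        return "\n".join(lines)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("load")
def _load_plates(config: RunConfig) -> dict[str, object]:
    plates = {}
    if config.simulate:
        for tissue in ("plasma", "retina"):
            plates[tissue] = simulate_luminex_plate(
                config.sim, tissue=tissue, panel=config.panel
            )
    else:
        if config.plasma_path:
            plates["plasma"] = pio.read_plate(
                config.plasma_path, config.panel,
                averaged=config.averaged_inputs, tissue="plasma",
            )
        if config.retina_path:
            plates["retina"] = pio.read_plate(
                config.retina_path, config.panel,
                averaged=config.averaged_inputs, tissue="retina",
            )
    return plates


def run_pipeline(config: RunConfig) -> PipelineBundle:
    """Run the full analysis and return the in-memory bundle.

    Any stage failure raises :class:`PipelineError` naming the stage; no
    partial outputs are written (writing only happens in ``bundle.write``).
    """
    plates = _load_plates(config)

    matrices: dict[str, NormalizedMatrix] = {}
    screens: dict[str, ImmuneScreenResults] = {}
    clusters: dict[str, ClusterResult] = {}
    segregation: dict[str, float] = {}

    normalize = _stage("normalize")(
        lambda plate: chex_normalize(average_duplicates(plate))
    )
    screen_stage = _stage("screen")(
        lambda m: run_screen(m, config.group, statistic=config.statistic,
                             sided=config.sided, q=config.q)
    )

    @_stage("cluster")
    def cluster_stage(matrix: NormalizedMatrix):
        cres = hier_cluster(matrix, axis="samples",
                            method=config.cluster_method,
                            metric=config.cluster_metric)
        score = segregation_score(
            cres, matrix.meta["group"], target=config.group
        )
        return cres, score

    for tissue, plate in plates.items():
        matrices[tissue] = normalize(plate)
        screens[tissue] = screen_stage(matrices[tissue])
        clusters[tissue], segregation[tissue] = cluster_stage(matrices[tissue])
        logger.info("%s: %d primary hits, %d secondary, segregation %.3f",
                    tissue, len(screens[tissue].primary_hits),
                    len(screens[tissue].secondary_hits), segregation[tissue])

    venn = None
    if "plasma" in screens and "retina" in screens:
        venn = venn_partition(
            screens["plasma"].primary_hits, screens["retina"].primary_hits
        )

    oct_results = None
    histology_summary = None
    tunel_anova = None

    if config.simulate or config.oct_path:
        @_stage("octstats")
        def oct_stage():
            table = (
                simulate_oct_table(config.sim)
                if config.simulate
                else pd.read_csv(config.oct_path, sep="\t")
            )
            return RetinalThicknessStudy(table).fit()
        oct_results = oct_stage()

    if config.simulate or config.histology_path:
        @_stage("histology")
        def hist_stage():
            table = (
                simulate_histology(config.sim)
                if config.simulate
                else pd.read_csv(config.histology_path, sep="\t")
            )
            measures = [c for c in table.columns
                        if c not in ("animal", "group") and not c.startswith("TUNEL_")]
            rows = []
            groups = list(dict.fromkeys(table["group"]))
            for m in measures:
                by_group = [table.loc[table["group"] == g, m].to_numpy(float)
                            for g in groups]
                res = anova_tukey(by_group, labels=groups)
                for g, vals in zip(groups, by_group):
                    s = group_summary(vals)
                    rows.append({"measure": m, "group": g, "mean": s.mean,
                                 "sem": s.sem, "n": s.n,
                                 "anova_F": res.F, "anova_p": res.p})
            summary = pd.DataFrame(rows)
            tunel_cols = [c for c in table.columns if c.startswith("TUNEL_")]
            anova = None
            if tunel_cols:
                long = table.melt(
                    id_vars=["animal", "group"], value_vars=tunel_cols,
                    var_name="layer", value_name="count",
                )
                long["layer"] = long["layer"].str.removeprefix("TUNEL_")
                anova = two_way_anova(long, "count", "layer", "group")
            return summary, anova
        histology_summary, tunel_anova = hist_stage()

    return PipelineBundle(
        config=config,
        matrices=matrices,
        screens=screens,
        venn=venn,
        clusters=clusters,
        segregation=segregation,
        oct_results=oct_results,
        histology_summary=histology_summary,
        tunel_anova=tunel_anova,
    )
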