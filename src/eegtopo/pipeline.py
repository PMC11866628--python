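"""End-to-end study analysis: recordings -> adjacency -> metrics -> statistics.

The stages run in a fixed order — preprocessing, band-specific imaginary
coherence adjacency matrices, sparsity-swept global graph metrics,
pre-normalized active-vs-sham statistics — first in memory
(:func:`analyze_study`) and, for file-based runs, wrapped with manifest
reading, CSV/JSON output and a provenance manifest
(:func:`run_pipeline`). Every stochastic stage derives its seed from the
master seed by stable hashing of the stage name and recording identity,
so identical configuration and seed reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rec_io
from .graphmetrics import (
    DEFAULT_N_NULL,
    DEFAULT_SPARSITY_GRID,
    DEFAULT_SWAPS_PER_EDGE,
    METRIC_NAMES,
    MetricCurves,
    sweep_metrics,
)
from .preprocess import CleaningReport, PreprocessParams, preprocess
from .recording import Condition, Recording, Segment, Side
from .spectral import (
    BANDS,
    DEFAULT_EPOCH_LENGTH,
    DEFAULT_HALF_BANDWIDTH,
    DEFAULT_PHASE_TOL,
    connectivity,
)
from .stats import (
    NormalizedChange,
    SignificanceMap,
    SummaryRow,
    compare_conditions,
    normalized_change,
    summarize_significance,
    summary_to_markdown,
)


def derive_seed(master: int, *context: str) -> int:
    """Stable per-stage, per-recording seed below 2**31."""
    tag = ":".join(context)
    return (int(master) ^ zlib.crc32(tag.encode())) % (2**31)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable knobs of the analysis stages (montage-independent)."""

    epoch_length: float = DEFAULT_EPOCH_LENGTH
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH
    phase_tol: float = DEFAULT_PHASE_TOL
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    sparsity_grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID
    n_null: int = DEFAULT_N_NULL
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    alpha: float = 0.05
    preprocessing: PreprocessParams | None = None  # None = recordings already clean
    seed: int = 0


def reduced_analysis_params(
    seed: int = 0,
    n_null: int = 4,
    sparsity_grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    alpha: float = 0.05,
) -> AnalysisParams:
    """Desk-scale analysis profile matching `synth.reduced_design` recordings:
    2-s epochs with 2-Hz half-bandwidth (7 tapers) and a small null ensemble."""
    return AnalysisParams(
        epoch_length=2.0,
        half_bandwidth=2.0,
        sparsity_grid=sparsity_grid,
        n_null=n_null,
        alpha=alpha,
        seed=seed,
    )


@dataclass
class StudyResult:
    """Everything the analysis produces, keyed by recording identity."""

    adjacency: dict[tuple, list]  # key -> list[BandAdjacency]
    curves: dict[tuple, MetricCurves]  # (subject, condition, side, segment)
    changes: dict[tuple, NormalizedChange]  # (subject, condition, side)
    significance: dict[str, SignificanceMap]  # side -> map
    summary: list[SummaryRow]
    cleaning: dict[tuple, CleaningReport] = field(default_factory=dict)

    def curves_frame(self) -> pd.DataFrame:
        """Long-format table: subject, condition, side, segment, band,
        sparsity, metric, value."""
        rows = []
        for (subj, cond, side, seg), mc in sorted(self.curves.items()):
            for m, metric in enumerate(mc.metrics):
                for b, band in enumerate(mc.bands):
                    for s, sp in enumerate(mc.sparsity_grid):
                        rows.append((subj, cond, side, seg, band, sp, metric,
                                     mc.values[m, b, s]))
        return pd.DataFrame(
            rows,
            columns=["subject", "condition", "side", "segment", "band",
                     "sparsity", "metric", "value"],
        )

    def significance_frame(self) -> pd.DataFrame:
        frames = [m.to_frame() for _, m in sorted(self.significance.items())]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def analyze_recording(rec: Recording, params: AnalysisParams) -> tuple[list, MetricCurves]:
    """One recording -> (band adjacencies, metric curves)."""
    adj = connectivity(
        rec,
        epoch_length=params.epoch_length,
        half_bandwidth=params.half_bandwidth,
        bands=params.bands,
        phase_tol=params.phase_tol,
    )
    seed = derive_seed(params.seed, "gta", *rec.key)
    mc = sweep_metrics(
        adj, grid=params.sparsity_grid, n_null=params.n_null,
        seed=seed, swaps_per_edge=params.swaps_per_edge,
    )
    return adj, mc


def analyze_study(
    recordings: list[Recording], params: AnalysisParams | None = None
) -> StudyResult:
    """Full analysis of a pre/post x active/sham recording collection."""
    params = params or AnalysisParams()
    adjacency: dict[tuple, list] = {}
    curves: dict[tuple, MetricCurves] = {}
    cleaning: dict[tuple, CleaningReport] = {}
    for rec in recordings:
        if rec.key in curves:
            raise ValueError(f"duplicate recording for {rec.key}")
        work = rec
        if params.preprocessing is not None:
            work, report = preprocess(work, params.preprocessing)
            cleaning[rec.key] = report
        adj, mc = analyze_recording(work, params)
        adjacency[rec.key] = adj
        curves[rec.key] = mc

    changes: dict[tuple, NormalizedChange] = {}
    arms: set[tuple[str, str, str]] = {
        (subj, cond, side) for (subj, cond, side, _seg) in curves
    }
    for subj, cond, side in sorted(arms):
        pre_key = (subj, cond, side, Segment.PRE.value)
        post_key = (subj, cond, side, Segment.POST.value)
        if pre_key not in curves or post_key not in curves:
            missing = "pre" if pre_key not in curves else "post"
            raise ValueError(
                f"subject {subj!r} condition {cond!r}/{side!r} is missing its "
                f"{missing} recording"
            )
        changes[(subj, cond, side)] = normalized_change(curves[pre_key], curves[post_key])

    significance: dict[str, SignificanceMap] = {}
    sides = sorted({side for (_s, _c, side) in changes})
    for side in sides:
        active = {s: nc for (s, c, sd), nc in changes.items()
                  if sd == side and c == Condition.ACTIVE.value}
        sham = {s: nc for (s, c, sd), nc in changes.items()
                if sd == side and c == Condition.SHAM.value}
        if not active or not sham:
            continue  # one-armed side: nothing to compare
        significance[side] = compare_conditions(active, sham, alpha=params.alpha, side=side)

    summary: list[SummaryRow] = []
    for side in sorted(significance):
        summary.extend(summarize_significance(significance[side]))
    return StudyResult(
        adjacency=adjacency, curves=curves, changes=changes,
        significance=significance, summary=summary, cleaning=cleaning,
    )


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class ManifestEntry:
    subject: str
    condition: str
    side: str
    segment: str
    path: str


@dataclass
class PipelineConfig:
    """File-based run configuration; see `PipelineConfig.from_json`."""

    manifest: list[ManifestEntry]
    out_dir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)
    montage: str | None = "standard-19"  # validate/normalize channel order on read

    def validate(self) -> None:
        if not self.manifest:
            raise ValueError("manifest is empty")
        seen = set()
        for e in self.manifest:
            Condition(e.condition), Side(e.side), Segment(e.segment)
            key = (e.subject, e.condition, e.side, e.segment)
            if key in seen:
                raise ValueError(f"duplicate manifest entry for {key}")
            seen.add(key)
        for subj, cond, side, seg in list(seen):
            other = "post" if seg == "pre" else "pre"
            if (subj, cond, side, other) not in seen:
                raise ValueError(
                    f"manifest missing {other} recording for subject {subj!r}, "
                    f"condition {cond!r}/{side!r}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        manifest = [ManifestEntry(**e) for e in raw["manifest"]]
        p = raw.get("params", {})
        if "preprocessing" in p and p["preprocessing"] is not None:
            p["preprocessing"] = PreprocessParams(**p["preprocessing"])
        if "sparsity_grid" in p:
            p["sparsity_grid"] = tuple(p["sparsity_grid"])
        if "bands" in p:
            p["bands"] = {k: tuple(v) for k, v in p["bands"].items()}
        return cls(manifest=manifest, out_dir=raw["out_dir"], params=AnalysisParams(**p),
                   montage=raw.get("montage", "standard-19"))

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "manifest": [dataclasses.asdict(e) for e in self.manifest],
                "params": _params_dict(self.params),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _params_dict(params: AnalysisParams) -> dict:
    d = dataclasses.asdict(params)
    d["sparsity_grid"] = list(params.sparsity_grid)
    return d


def run_pipeline(cfg: PipelineConfig) -> StudyResult:
    """Read the manifest, run the full analysis, write the result bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expected = None
    if cfg.montage == "standard-19":
        from .montage import STANDARD_1020_LABELS

        expected = STANDARD_1020_LABELS
    recordings = []
    for e in cfg.manifest:
        try:
            rec = rec_io.read_recording(e.path, expected_labels=expected)
        except Exception as exc:
            raise RuntimeError(
                f"stage=read subject={e.subject} condition={e.condition}: {exc}"
            ) from exc
        rec.subject_id = e.subject
        rec.condition = Condition(e.condition)
        rec.side = Side(e.side)
        rec.segment = Segment(e.segment)
        recordings.append(rec)

    result = analyze_study(recordings, cfg.params)

    adj_dir = out / "adjacency"
    adj_dir.mkdir(exist_ok=True)
    for key, adj_list in sorted(result.adjacency.items()):
        stem = "_".join(key)
        for adj in adj_list:
            df = pd.DataFrame(adj.W, index=list(adj.labels), columns=list(adj.labels))
            df.to_csv(adj_dir / f"{stem}_{adj.band}.csv", float_format="%.10g")

    result.curves_frame().to_csv(out / "metric_curves.csv", index=False,
                                 float_format="%.10g")
    result.significance_frame().to_csv(out / "significance.csv", index=False,
                                       float_format="%.10g")
    (out / "summary.md").write_text(summary_to_markdown(result.summary) + "\n")
    (out / "summary.json").write_text(json.dumps(
        [dataclasses.asdict(r) for r in result.summary], indent=1))
    if result.cleaning:
        (out / "cleaning_reports.json").write_text(json.dumps(
            {"_".join(k): v.as_dict() for k, v in sorted(result.cleaning.items())},
            indent=1))
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.params.seed,
        "n_recordings": len(recordings),
        "metrics": list(METRIC_NAMES),
        "bands": list(cfg.params.bands),
        "sparsity_grid": list(cfg.params.sparsity_grid),
        "alpha": cfg.params.alpha,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
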