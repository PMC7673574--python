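"""End-to-end orchestration: distances -> barcode gap -> richness -> tree.

``run_pipeline`` executes every stage on the three input files, writes
machine-readable reports (TSV/JSON, no figures — the TSVs are plot-ready)
and a manifest recording package version, seed, parameters and input
checksums.  Outputs are deterministic for identical inputs and seed, so a
re-run is byte-identical.  Any stage error aborts the run, removes partial
outputs and re-raises with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .barcode_gap import (
    compare_floras,
    distance_histogram,
    min_interspecific_distances,
)
from .distances import (
    DEFAULT_MIN_OVERLAP,
    alignment_stats,
    build_distance_matrix,
)
from .io import read_aligned_fasta, read_checklist, read_incidence
from .phylo import (
    assess_monophyly,
    midpoint_root,
    neighbor_joining,
    prune_undefined,
    write_newick,
)
from .richness import accumulation
from .summary import summarize_checklist

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("pteridosurvey")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    alignment: str
    checklist: str
    out_dir: str
    incidence: str | None = None
    min_overlap: int = DEFAULT_MIN_OVERLAP
    exclude_nonnative: bool = False
    bootstrap: int = 1000
    level: float = 0.95
    endpoint: int | None = None
    bin_width: float = 0.005
    area_ha: float | None = None
    build_tree: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file ('#' starts a comment)."""
        kwargs: dict = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, value = (tok.strip() for tok in line.split("=", 1))
            kwargs[key] = value
        return cls(**_coerce_config(kwargs))


def _coerce_config(kwargs: dict) -> dict:
    casts = {
        "min_overlap": int,
        "bootstrap": int,
        "seed": int,
        "endpoint": int,
        "level": float,
        "bin_width": float,
        "area_ha": float,
        "exclude_nonnative": lambda v: v.lower() in ("true", "yes", "1"),
        "build_tree": lambda v: v.lower() in ("true", "yes", "1"),
    }
    out = {}
    for key, value in kwargs.items():
        out[key] = casts[key](value) if key in casts else value
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write reports under ``cfg.out_dir``.

    Returns the in-memory results keyed by stage.  On any stage failure the
    files written so far are removed and ``PipelineError`` is raised.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    stage = "read-inputs"
    try:
        aln = read_aligned_fasta(cfg.alignment)
        checklist = read_checklist(cfg.checklist)
        inc = read_incidence(cfg.incidence) if cfg.incidence else None

        stage = "alignment-stats"
        stats = alignment_stats(aln)
        results["alignment_stats"] = stats
        emit(
            "alignment_stats.json",
            lambda p: Path(p).write_text(
                json.dumps(asdict(stats), indent=2, sort_keys=True) + "\n"
            ),
        )

        stage = "distances"
        dm = build_distance_matrix(aln, min_overlap=cfg.min_overlap)
        results["distance_matrix"] = dm
        emit("distances_long.tsv", dm.write_long_tsv)

        stage = "barcode-gap"
        report = min_interspecific_distances(
            dm, checklist, exclude_nonnative=cfg.exclude_nonnative
        )
        results["gap_report"] = report
        emit("gap_report.tsv", report.write_tsv)
        emit("gap_summary.json", report.write_summary_json)
        hist = distance_histogram(report, bin_width=cfg.bin_width)
        results["gap_histogram"] = hist
        emit("gap_histogram.tsv", hist.write_tsv)

        floras = checklist.floras
        if len(floras) > 1:
            stage = "compare-floras"
            per_flora = compare_floras(
                aln,
                checklist,
                min_overlap=cfg.min_overlap,
                exclude_nonnative=cfg.exclude_nonnative,
            )
            results["per_flora"] = per_flora
            for label, rep in per_flora.items():
                emit(f"gap_{label}.tsv", rep.write_tsv)
                emit(f"gap_{label}_summary.json", rep.write_summary_json)

        if inc is not None:
            stage = "richness"
            acc = accumulation(
                inc,
                endpoint=cfg.endpoint,
                B=cfg.bootstrap,
                level=cfg.level,
                seed=cfg.seed,
            )
            results["richness"] = acc
            emit("richness_curve.tsv", acc.write_curve_tsv)
            emit("richness_summary.json", acc.write_summary_json)

        if cfg.build_tree:
            stage = "tree"
            dm_tree, removed = prune_undefined(dm)
            if removed:
                logger.warning(
                    "tree stage: removed %d specimen(s) with undefined "
                    "pairwise distances: %s",
                    len(removed),
                    ", ".join(removed),
                )
            tree = midpoint_root(neighbor_joining(dm_tree))
            results["tree"] = tree
            results["tree_pruned_specimens"] = removed
            emit("tree.nwk", lambda p: write_newick(tree, p))

            stage = "monophyly"
            mono = assess_monophyly(tree, checklist, allow_missing=True)
            results["monophyly"] = mono
            emit(
                "monophyly.tsv",
                lambda p: Path(p).write_text(
                    "taxon\tstatus\n"
                    + "".join(
                        f"{t}\t{s}\n" for t, s in sorted(mono.items())
                    )
                ),
            )

        stage = "summary"
        summary = summarize_checklist(
            checklist,
            alignment=aln,
            exclude_nonnative=cfg.exclude_nonnative,
            area_ha=cfg.area_ha,
        )
        results["summary"] = summary
        emit("summary.json", summary.write_json)

        stage = "manifest"
        manifest = {
            "package": "pteridosurvey",
            "version": __version__,
            "seed": cfg.seed,
            "parameters": {
                "min_overlap": cfg.min_overlap,
                "exclude_nonnative": cfg.exclude_nonnative,
                "bootstrap": cfg.bootstrap,
                "level": cfg.level,
                "endpoint": cfg.endpoint,
                "bin_width": cfg.bin_width,
                "area_ha": cfg.area_ha,
                "build_tree": cfg.build_tree,
            },
            "inputs": {
                "alignment": _sha256(cfg.alignment),
                "checklist": _sha256(cfg.checklist),
                "incidence": _sha256(cfg.incidence)
                if cfg.incidence
                else None,
            },
        }
        emit(
            "manifest.json",
            lambda p: Path(p).write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            ),
        )
        results["manifest"] = manifest
    except Exception as exc:  # noqa: BLE001 - abort semantics
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    logger.info("pipeline complete: %d report files", len(written))
    return results
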