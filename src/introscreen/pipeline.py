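"""End-to-end orchestration: QC -> ancestry scoring -> hybrid classification
-> (optional) population-genomic baseline, from one structured config.

Outputs are deterministic for a given config and seed — no timestamps are
written — so re-running an unchanged config rewrites byte-identical files.
A JSON manifest records the package version, a hash of the resolved config,
the seed, and every artifact written; a stage failure leaves a FAILED
marker next to the partial outputs and yields a non-zero status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestry import score_matrix, summarize_population, summary_frame
from .hybrid import CLASSES, MCMCConfig, gibbs_classify
from .io import load_genotypes, load_panel, write_genotypes
from .panel_qc import QCConfig, apply_qc_filters, panel_summary
from .popgen import FilterConfig, filter_dataset, fst_matrix, full_stats, stats_frame

log = logging.getLogger("introscreen.pipeline")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (flat YAML document on disk)."""

    genotypes: str
    popmap: str
    out_dir: str
    panel: str | None = None
    depths: str | None = None
    format: str = "tsv"
    seed: int = 0
    threshold: float = 0.8
    log_level: str = "INFO"
    stages: dict = field(
        default_factory=lambda: {"qc": True, "score": True, "classify": True, "popgen": False}
    )
    qc: QCConfig = field(default_factory=QCConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        paths = raw.pop("paths", {})
        raw.setdefault("genotypes", paths.get("genotypes"))
        raw.setdefault("popmap", paths.get("popmap"))
        raw.setdefault("out_dir", paths.get("out_dir", "introscreen_out"))
        raw.setdefault("panel", paths.get("panel"))
        raw.setdefault("depths", paths.get("depths"))
        if isinstance(raw.get("qc"), dict):
            raw["qc"] = QCConfig(**raw["qc"])
        if isinstance(raw.get("filter"), dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if isinstance(raw.get("mcmc"), dict):
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> tuple[int, dict]:
    """Execute the configured stages; returns (exit status, manifest)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": {},
    }

    for p, name in ((cfg.genotypes, "genotypes"), (cfg.popmap, "popmap")):
        if p is None or not Path(p).exists():
            log.error("required input %s missing: %r", name, p)
            return 2, manifest
    if cfg.panel is not None and not Path(cfg.panel).exists():
        log.error("panel path does not exist: %r", cfg.panel)
        return 2, manifest

    def _fail(stage: str, exc: Exception) -> tuple[int, dict]:
        log.error("stage %s failed: %s", stage, exc)
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        manifest["failed_stage"] = stage
        _write_manifest(out_dir, manifest)
        return 1, manifest

    try:
        panel = load_panel(cfg.panel) if cfg.panel else None
        matrix = load_genotypes(
            cfg.genotypes, cfg.popmap, format=cfg.format, panel=panel, depths=cfg.depths
        )
    except Exception as exc:  # noqa: BLE001 - any load failure aborts the run
        return _fail("load", exc)

    if cfg.stages.get("qc", True):
        try:
            qc_cfg = cfg.qc
            if matrix.depths is None and qc_cfg.min_locus_depth > 0:
                qc_cfg = dataclasses.replace(qc_cfg, min_locus_depth=0.0)
                log.info("no depth table; skipping the coverage filter")
            matrix, report = apply_qc_filters(matrix, qc_cfg)
            _write_tsv_rows(
                out_dir / "panel_summary.tsv",
                [s.__dict__ for s in panel_summary(matrix)],
            )
            (out_dir / "qc_report.json").write_text(
                json.dumps(
                    {
                        "dropped_loci": report.dropped_loci,
                        "dropped_samples": report.dropped_samples,
                    },
                    indent=2,
                )
            )
            write_genotypes(matrix, out_dir / "genotypes_filtered.tsv")
            manifest["outputs"]["qc"] = [
                "panel_summary.tsv",
                "qc_report.json",
                "genotypes_filtered.tsv",
            ]
        except Exception as exc:  # noqa: BLE001
            return _fail("qc", exc)

    scores = None
    if cfg.stages.get("score", True):
        try:
            scores = score_matrix(matrix)
            _write_tsv_rows(
                out_dir / "ancestry_scores.tsv",
                [
                    {
                        "sample": s.sample_id,
                        "population": matrix.pops[s.sample_id],
                        "ancestry": s.reported,
                        "ancestry_raw": s.score,
                        "n_het": s.n_het,
                        "n_hom_foreign": s.n_hom_foreign,
                    }
                    for s in scores
                ],
            )
            summ = summarize_population(scores, matrix.pops)
            summary_frame(summ).to_csv(
                out_dir / "ancestry_by_population.tsv", sep="\t", index=False
            )
            manifest["outputs"]["score"] = [
                "ancestry_scores.tsv",
                "ancestry_by_population.tsv",
            ]
        except Exception as exc:  # noqa: BLE001
            return _fail("score", exc)

    if cfg.stages.get("classify", True):
        try:
            mcmc = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
            result = gibbs_classify(matrix, mcmc)
            rows = []
            for post, label in zip(result.posteriors, result.labels(cfg.threshold)):
                row = {
                    "sample": post.sample_id,
                    "population": matrix.pops[post.sample_id],
                }
                row.update({c: post.probs[c] for c in CLASSES})
                row["label"] = label.label
                row["top_prob"] = label.top_prob
                row["second_prob"] = label.second_prob
                rows.append(row)
            _write_tsv_rows(out_dir / "hybrid_classes.tsv", rows)
            manifest["outputs"]["classify"] = ["hybrid_classes.tsv"]
            if result.flagged:
                manifest["mcmc_flagged"] = result.flagged
        except Exception as exc:  # noqa: BLE001
            return _fail("classify", exc)

    if cfg.stages.get("popgen", False):
        try:
            filtered, freport = filter_dataset(matrix, cfg.filter)
            stats = full_stats(filtered)
            stats_frame(stats).to_csv(out_dir / "popgen_stats.tsv", sep="\t", index=False)
            outputs = ["popgen_stats.tsv"]
            if len(filtered.populations) > 1:
                fst_matrix(filtered).to_csv(out_dir / "fst_matrix.tsv", sep="\t")
                outputs.append("fst_matrix.tsv")
            manifest["outputs"]["popgen"] = outputs
            manifest["popgen_filter"] = {
                "dropped_presence": len(freport.dropped_presence),
                "dropped_mac": len(freport.dropped_mac),
                "dropped_linked": len(freport.dropped_linked),
            }
        except Exception as exc:  # noqa: BLE001
            return _fail("popgen", exc)

    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    _write_manifest(out_dir, manifest)
    return 0, manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write_tsv_rows(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
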