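"""End-to-end orchestration: trim -> distances -> delimitation -> reference
match -> concordance -> summaries, with a manifest for reproducibility.

Stage outputs are written to the run directory under fixed names
(``distances.tsv``, ``partition_<method>.tsv``, ``matches.tsv``,
``discordances.tsv``, ``summary.tsv``, ``provisional.tsv``, ``report.json``,
``manifest.json``) so any downstream stage can be resumed from disk.  The
manifest records input checksums, the configuration echo and per-stage
status; for a fixed seed a rerun reproduces identical output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .concordance import (
    DiscordanceRecord,
    ProvisionalVerdict,
    classify_discordances,
    resolve_provisional,
    summarize,
)
from .delimit import AbgdParams, abgd_partition, abgd_scan, single_linkage_partition
from .distances import DistanceMatrix, p_distance_matrix, trim_to_common_overlap
from .gmyc import gmyc_single_threshold
from .io import (
    Partition,
    Provenance,
    cross_validate,
    read_alignment,
    read_metadata,
    read_partition,
    read_ultrametric_tree,
    write_partition,
)
from .refmatch import best_match_table, flag_first_barcode, flag_novelty, normalize_name

__all__ = ["RunConfig", "RunResult", "run_all"]

log = logging.getLogger("barconcord")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    At least one delimitation method must be enabled (a toggle or an imported
    partition file).  The seed feeds every stochastic step.
    """

    alignment: str
    metadata: str
    out_dir: str
    tree: str | None = None
    imported_partitions: tuple[str, ...] = ()
    run_abgd: bool = True
    run_linkage: bool = True
    run_gmyc: bool = True  # ignored without a tree
    min_common: int = 150
    min_overlap: int = 100
    abgd_prior: float = 0.02
    abgd_gap_width: float = 1.0
    linkage_threshold: float = 0.022
    match_min_similarity: float = 0.80
    match_max: int = 100
    novelty_threshold: float = 0.05
    provisional_threshold: float = 0.05
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if not (
            self.run_abgd
            or self.run_linkage
            or (self.run_gmyc and self.tree)
            or self.imported_partitions
        ):
            raise ValueError("at least one delimitation method must be enabled")


@dataclass
class RunResult:
    out_dir: Path
    partitions: list[Partition]
    discordances: list[DiscordanceRecord]
    provisional: list[ProvisionalVerdict]
    novelty: set[str]
    first_barcodes: set[str]
    manifest: dict
    report: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    fmt = logging.Formatter("%(asctime)s [%(stage)s] %(message)s")
    handler.setFormatter(fmt)
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(fmt)
        log.addHandler(stream)
    log.setLevel(logging.INFO)
    return handler


def _stage(name: str, message: str) -> None:
    log.info(message, extra={"stage": name})


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; raises on stage failure after writing a
    manifest that records the failure point (partial outputs preserved)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "outputs": {},
        "stages": {},
    }
    for key in ("alignment", "metadata", "tree"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = _sha256(Path(path))
    for p in config.imported_partitions:
        manifest["inputs"][f"partition:{Path(p).name}"] = _sha256(Path(p))

    def finish_manifest() -> None:
        for written in sorted(out.iterdir()):
            if written.name in ("manifest.json", "run.log"):
                continue
            manifest["outputs"][written.name] = _sha256(written)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )

    current = "validate"
    try:
        # ---- load + validate
        sequences = read_alignment(config.alignment)
        records = read_metadata(config.metadata)
        tree = read_ultrametric_tree(config.tree) if config.tree else None
        imported = [read_partition(p) for p in config.imported_partitions]
        report_val = cross_validate(
            sequences, records, [tree] if tree else None, imported,
            strict=config.strict,
        )
        (out / "validation.json").write_text(report_val.to_json(),
                                             encoding="utf-8")
        manifest["stages"][current] = "ok"
        _stage(current, f"{len(sequences)} sequences, {len(records)} specimens")

        # ---- trim + distances
        current = "distances"
        kept, removed = trim_to_common_overlap(sequences, config.min_common)
        dm = p_distance_matrix(kept, config.min_overlap)
        dm.write_tsv(out / "distances.tsv")
        manifest["stages"][current] = "ok"
        _stage(current, f"kept {len(kept)}, removed {len(removed)} short sequences")

        # ---- delimitation
        current = "delimit"
        partitions: list[Partition] = []
        scan_summary = None
        if config.run_abgd:
            partitions.append(
                abgd_partition(dm, config.abgd_prior, config.abgd_gap_width)
            )
            scan = abgd_scan(dm, AbgdParams(
                relative_gap_width=config.abgd_gap_width))
            scan_summary = [
                {"prior": prior, "n_groups": k} for prior, _, k in scan
            ]
        if config.run_linkage:
            partitions.append(
                single_linkage_partition(dm, config.linkage_threshold)
            )
        gmyc_fit = None
        if config.run_gmyc and tree is not None:
            gmyc_fit = gmyc_single_threshold(tree)
            partitions.append(gmyc_fit.partition)
            (out / "gmyc.json").write_text(
                json.dumps(gmyc_fit.to_dict(), indent=2, sort_keys=True),
                encoding="utf-8",
            )
        partitions.extend(imported)
        for part in partitions:
            write_partition(part, out / f"partition_{part.method_name}.tsv")
        manifest["stages"][current] = "ok"
        _stage(current, f"methods: {[p.method_name for p in partitions]}")

        # ---- reference match
        current = "match"
        matches = best_match_table(
            records, dm, config.match_max, config.match_min_similarity
        )
        novelty = flag_novelty(records, matches, config.novelty_threshold)
        ref_names = [
            r.morphospecies for r in records
            if r.provenance == Provenance.EXTERNAL and not r.provisional
        ]
        first = flag_first_barcode(records, ref_names)
        with open(out / "matches.tsv", "w", encoding="utf-8") as fh:
            fh.write("query_id\trank\treference_id\treference_name\t"
                     "p_distance\tclassification\n")
            for qid in sorted(matches):
                for rank, m in enumerate(matches[qid].matches, start=1):
                    fh.write(f"{qid}\t{rank}\t{m.reference_id}\t"
                             f"{m.reference_name}\t{m.distance:.8g}\t"
                             f"{m.classification}\n")
        manifest["stages"][current] = "ok"
        _stage(current, f"{len(novelty)} divergent morphospecies, "
                        f"{len(first)} first barcodes")

        # ---- concordance
        current = "concord"
        study_ids = {
            r.specimen_id for r in records if r.provenance == Provenance.STUDY
        }
        parts_study = [p.restrict(study_ids) for p in partitions]
        discordances = classify_discordances(records, parts_study, partitions)
        provisional_labels = sorted({
            normalize_name(r.morphospecies)
            for r in records
            if r.provisional and r.provenance == Provenance.STUDY
        })
        verdicts = [
            resolve_provisional(name, partitions, records, matches,
                                config.provisional_threshold)
            for name in provisional_labels
        ]
        tables = summarize(records, partitions, discordances)
        with open(out / "discordances.tsv", "w", encoding="utf-8") as fh:
            fh.write("morphospecies\tdescription\tcode\n")
            for rec in sorted(discordances, key=lambda r: r.morphospecies):
                fh.write(f"{', '.join(rec.morphospecies)}\t{rec.detail}\t"
                         f"{rec.code}\n")
        with open(out / "provisional.tsv", "w", encoding="utf-8") as fh:
            fh.write("morphospecies\tstatus\tgrouped_with\treference_note\n")
            for v in verdicts:
                fh.write(f"{v.morphospecies}\t{v.status}\t"
                         f"{', '.join(v.grouped_with)}\t{v.reference_note}\n")
        tables.by_class.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest["stages"][current] = "ok"
        n_disc = sum(
            1 for r in discordances if r.category != "CONCORDANT"
        )
        _stage(current, f"{n_disc} discordance records")

        # ---- consolidated report
        current = "report"
        report = {
            "n_sequences": len(sequences),
            "n_kept": len(kept),
            "removed_short": removed,
            "methods": {p.method_name: p.n_groups() for p in partitions},
            "putative_species_study": {
                p.method_name: p.n_groups() for p in parts_study
            },
            "abgd_scan": scan_summary,
            "gmyc": gmyc_fit.to_dict() if gmyc_fit else None,
            "novelty": sorted(novelty),
            "first_barcodes": sorted(first),
            "discordances": [
                {
                    "morphospecies": list(r.morphospecies),
                    "category": r.category,
                    "code": r.code,
                    "methods": sorted(r.methods_triggering),
                    "detail": r.detail,
                }
                for r in sorted(discordances, key=lambda r: r.morphospecies)
            ],
            "provisional": [
                {
                    "morphospecies": v.morphospecies,
                    "status": v.status,
                    "grouped_with": list(v.grouped_with),
                    "reference_note": v.reference_note,
                }
                for v in verdicts
            ],
            "summary_by_class": tables.by_class.to_dict(orient="records"),
            "discordance_tally": tables.discordance_tally.to_dict(
                orient="records"
            ),
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
        manifest["stages"][current] = "ok"
    except Exception as exc:
        manifest["stages"][current] = f"failed: {exc}"
        finish_manifest()
        log.removeHandler(handler)
        raise
    finish_manifest()
    log.removeHandler(handler)
    return RunResult(
        out_dir=out,
        partitions=partitions,
        discordances=discordances,
        provisional=verdicts,
        novelty=novelty,
        first_barcodes=first,
        manifest=manifest,
        report=report,
    )
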