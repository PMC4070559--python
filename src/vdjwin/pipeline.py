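"""End-to-end orchestration: reads in, clone report out.

Runs index building, per-read window prediction, window counting,
optional clustering, clone selection, representative computation and
V(D)J designation, and writes the report files (windows.tsv, stats.tsv,
clones.tsv, clones.json, representatives.fasta). All coordinates in
outputs are 0-based half-open; everything is deterministic for fixed
inputs and configuration.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .clustering import (
    CloneTable,
    ClusterParams,
    cluster_windows,
    count_windows,
    select_clones,
)
from .germline import GermlineDB
from .index import KmerIndex
from .representative import RepresentativeParams, representative_region
from .segmentation import (
    AlignmentScoring,
    format_designation,
    segment_sequence,
)
from .simulate import CloneTruth, ReadTruth
from .windows import SegStatus, WindowHit, WindowParams, predict_window

_FASTQ_EXTS = (".fq", ".fastq", ".fq.gz", ".fastq.gz")


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, plain or gzipped; the
    format is taken from the file extension. Qualities are ignored."""
    path = Path(path)
    name = path.name.lower()
    fmt = "fastq" if name.endswith(_FASTQ_EXTS) else "fasta"
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


@dataclass
class RunConfig:
    """One pipeline run. Defaults are the conventional ones for each
    stage: w from the locus, zero clustering tolerance, top 20 clones of
    at least 10 reads, representative k equal to the seed weight."""

    db: GermlineDB
    window: WindowParams | None = None
    cluster: ClusterParams = dc_field(default_factory=ClusterParams)
    representative: RepresentativeParams | None = None
    scoring: AlignmentScoring = dc_field(default_factory=AlignmentScoring)
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.window is None:
            self.window = WindowParams(w=self.db.w)
        if self.representative is None:
            self.representative = RepresentativeParams(k_rep=self.db.seed.weight)


@dataclass
class RunReport:
    status_counts: dict[str, int]
    table: CloneTable  # selected clones, fully annotated
    full_table: CloneTable  # all clones after clustering, before selection
    n_reads: int
    hits: list[WindowHit]

    @property
    def total_segmented(self) -> int:
        return self.table.total_segmented

    @property
    def segmented_fraction(self) -> float:
        return self.total_segmented / self.n_reads if self.n_reads else 0.0


def run_pipeline(
    config: RunConfig, reads: Iterable[tuple[str, str]]
) -> RunReport:
    """Execute the full two-stage analysis over an (id, sequence) stream."""
    idx = KmerIndex.build(config.db)
    status_counts: Counter[str] = Counter()
    hits: list[WindowHit] = []
    oriented_by_window: dict[str, list[str]] = {}
    segmented: list[WindowHit] = []
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        hit, oriented = predict_window(idx, read_id, seq, config.window)
        status_counts[hit.status.value] += 1
        hits.append(hit)
        if hit.status is SegStatus.SEGMENTED:
            segmented.append(hit)
            oriented_by_window.setdefault(hit.window, []).append(oriented)

    table = count_windows(segmented)
    table = cluster_windows(table, config.cluster)
    selected = select_clones(table, config.cluster)

    for clone in selected.clones:
        clone_reads = [
            r for w in sorted(clone.window_counts) for r in oriented_by_window[w]
        ]
        clone.representative = representative_region(
            clone_reads, clone.seed_window, config.representative
        )
        clone.designation = segment_sequence(
            clone.representative, config.db, config.scoring
        )

    report = RunReport(
        status_counts=dict(status_counts),
        table=selected,
        full_table=table,
        n_reads=n_reads,
        hits=hits,
    )
    if config.out_dir is not None:
        write_report(report, config)
    return report


# ---- report files ------------------------------------------------------


def write_report(report: RunReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "windows.tsv", "w") as fh:
        fh.write("# 0-based half-open coordinates; windows in V->J orientation\n")
        fh.write("read_id\tstatus\tstrand\tcenter\twindow\n")
        for h in report.hits:
            c = "" if h.center is None else h.center
            w = h.window or ""
            fh.write(f"{h.read_id}\t{h.status.value}\t{h.strand}\t{c}\t{w}\n")

    with open(out / "stats.tsv", "w") as fh:
        fh.write("status\tcount\n")
        for status in SegStatus:
            fh.write(f"{status.value}\t{report.status_counts.get(status.value, 0)}\n")
        fh.write(f"TOTAL\t{report.n_reads}\n")

    total = report.total_segmented or 1
    with open(out / "clones.tsv", "w") as fh:
        fh.write(
            "rank\tseed_window\tread_count\tfraction\tn_windows\t"
            "flags\tdesignation\n"
        )
        for rank, c in enumerate(report.table.clones, start=1):
            flags = "followed" if c.followed else ""
            desig = format_designation(c.designation) if c.designation else ""
            fh.write(
                f"{rank}\t{c.seed_window}\t{c.read_count}\t"
                f"{c.read_count / total:.6f}\t{len(c.window_counts)}\t"
                f"{flags}\t{desig}\n"
            )

    clones_json = []
    for rank, c in enumerate(report.table.clones, start=1):
        entry = {
            "rank": rank,
            "seed_window": c.seed_window,
            "read_count": c.read_count,
            "fraction": c.read_count / total,
            "member_windows": sorted(c.window_counts),
            "followed": c.followed,
            "representative": c.representative,
            "designation": None,
        }
        if c.designation:
            d = c.designation
            entry["designation"] = {
                "text": format_designation(d),
                "v_name": d.v_name,
                "v_del": d.v_del,
                "n_region": d.n_region,
                "j_del": d.j_del,
                "j_name": d.j_name,
                "v_end": d.v_end,
                "j_start": d.j_start,
                "score": d.score,
            }
        clones_json.append(entry)
    with open(out / "clones.json", "w") as fh:
        json.dump(
            {
                "n_reads": report.n_reads,
                "total_segmented": report.total_segmented,
                "status_counts": report.status_counts,
                "clones": clones_json,
            },
            fh,
            indent=1,
        )

    with open(out / "representatives.fasta", "w") as fh:
        for rank, c in enumerate(report.table.clones, start=1):
            if c.representative:
                fh.write(f">clone-{rank:03d} {c.seed_window}\n{c.representative}\n")


# ---- evaluation against simulator truth --------------------------------


def center_accuracy(
    hits: Sequence[WindowHit],
    truths: Sequence[ReadTruth],
    tolerance: int,
) -> float:
    """Fraction of evaluable reads whose predicted junction center lies
    strictly within ``tolerance`` bp of the true center.

    Evaluable = SEGMENTED with a truth-covered junction. Raises when the
    evaluation set is empty (the fraction would be undefined)."""
    truth_by_id = {t.read_id: t for t in truths}
    n = ok = 0
    for h in hits:
        if h.status is not SegStatus.SEGMENTED:
            continue
        t = truth_by_id.get(h.read_id)
        if t is None or t.true_center is None:
            continue
        n += 1
        if abs(h.center - t.true_center) < tolerance:
            ok += 1
    if n == 0:
        raise ValueError("no evaluable reads (disjoint ids or nothing segmented)")
    return ok / n


def center_distance_histogram(
    hits: Sequence[WindowHit], truths: Sequence[ReadTruth]
) -> dict[int, int]:
    """Histogram of |predicted - true| junction-center distances."""
    truth_by_id = {t.read_id: t for t in truths}
    histo: Counter[int] = Counter()
    for h in hits:
        if h.status is not SegStatus.SEGMENTED:
            continue
        t = truth_by_id.get(h.read_id)
        if t is None or t.true_center is None:
            continue
        histo[abs(h.center - t.true_center)] += 1
    return dict(sorted(histo.items()))


def abundance_recovery(
    table: CloneTable,
    clones: Sequence[CloneTruth],
    truths: Sequence[ReadTruth],
    idx: KmerIndex,
    params: WindowParams,
) -> list[dict]:
    """Per-clone (true fraction, estimated fraction), matched by window.

    Each simulated clone's expected window is obtained by running the
    pipeline's own window prediction on the true clone sequence; the
    estimate is that window's clone share of segmented reads. Simulated
    clones without a detected counterpart get estimate 0; detected clones
    matching no simulated window are flagged spurious."""
    from .windows import predict_window

    total_reads = len(truths)
    reads_per_clone = Counter(t.clone_id for t in truths)
    est_by_window = {
        c.seed_window: c.read_count / (table.total_segmented or 1)
        for c in table.clones
    }
    clone_by_window = {w: cl for cl in table.clones for w in cl.window_counts}

    out = []
    matched_windows: set[str] = set()
    for c in clones:
        hit, _ = predict_window(idx, c.clone_id, c.full_sequence, params)
        window = hit.window if hit.status is SegStatus.SEGMENTED else None
        cl = clone_by_window.get(window) if window else None
        est = (
            cl.read_count / (table.total_segmented or 1) if cl is not None else 0.0
        )
        if cl is not None:
            matched_windows.update(cl.window_counts)
        out.append(
            {
                "clone_id": c.clone_id,
                "window": window,
                "true_fraction": reads_per_clone[c.clone_id] / total_reads,
                "estimated_fraction": est,
                "spurious": False,
            }
        )
    for cl in table.clones:
        if not (set(cl.window_counts) & matched_windows):
            out.append(
                {
                    "clone_id": None,
                    "window": cl.seed_window,
                    "true_fraction": 0.0,
                    "estimated_fraction": est_by_window[cl.seed_window],
                    "spurious": True,
                }
            )
    return out
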