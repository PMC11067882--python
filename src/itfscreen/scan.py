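"""Tag scanning of barcoded reads and aggregation to UMI (transcript) level.

Reads carrying a cell barcode and a UMI are searched for exact (optionally
Hamming-tolerant, substitutions only) occurrences of any construct's
forward or reverse junction tag. Hits are grouped per (cell barcode, UMI)
— one captured transcript molecule — and each molecule is assigned to the
TF with the most supporting reads. Two exclusion rules apply at the
transcript level:

* ``tf_tie``           — two TFs tie for the most supporting reads;
* ``aligner_conflict`` — more than half of the molecule's reads were
  annotated by an external aligner to a gene different from the
  tag-derived TF. Reads the aligner left unannotated ("NA") never count
  as conflicting.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .tags import TagSpec, reverse_complement

logger = logging.getLogger(__name__)

#: value an external aligner uses for "no gene annotation"
NA_GENE = "NA"

#: default 10x-style mate-1 layout: 16 nt cell barcode then 12 nt UMI
DEFAULT_BARCODE_LEN = 16
DEFAULT_UMI_LEN = 12


@dataclass(frozen=True)
class TaggedRead:
    """One cDNA read with its cell barcode and UMI already extracted."""

    read_id: str
    cell_barcode: str
    umi: str
    sequence: str
    aligner_gene: str | None = None


@dataclass(frozen=True)
class TagHit:
    """One tag occurrence inside one read."""

    read_id: str
    tf_name: str
    orientation: str  # "forward" | "reverse" — which junction tag matched
    position: int     # 0-based offset of the match in the read as given
    mismatches: int


@dataclass
class UmiAssignment:
    """Transcript-level call: one (cell barcode, UMI) molecule -> one TF."""

    cell_barcode: str
    umi: str
    tf_name: str
    n_reads_supporting: int
    n_reads_total: int
    excluded: bool = False
    exclusion_reason: str = ""


def find_occurrences(sequence: str, pattern: str, max_mismatches: int = 0) -> list[tuple[int, int]]:
    """All (position, mismatches) where ``pattern`` matches ``sequence``.

    Substitutions only, no indels. Exact matching uses ``str.find``; the
    tolerant path compares windows with early exit.
    """
    n, m = len(sequence), len(pattern)
    if m == 0 or m > n:
        return []
    if max_mismatches == 0:
        out = []
        start = sequence.find(pattern)
        while start != -1:
            out.append((start, 0))
            start = sequence.find(pattern, start + 1)
        return out
    out = []
    for pos in range(n - m + 1):
        mm = 0
        for a, b in zip(sequence[pos:pos + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            out.append((pos, mm))
    return out


def scan_reads(
    reads: Iterable[TaggedRead],
    tags: Sequence[TagSpec],
    max_mismatches: int = 0,
    summary: dict | None = None,
) -> list[TagHit]:
    """Search every retained read for every tag in both orientations.

    Reads lacking a cell barcode or UMI are dropped before scanning and
    counted in ``summary`` (also logged). Each tag is searched as given and
    as its reverse complement, covering reads sequenced from either strand;
    duplicate hits (palindromic tags) are merged. When several mismatch
    counts are possible at one position, the smallest is reported.
    """
    if not tags:
        raise ValueError("tag table is empty")
    patterns: list[tuple[str, str, str]] = []  # (tf_name, orientation, pattern)
    for t in tags:
        for orientation, tag in (("forward", t.forward_tag), ("reverse", t.reverse_tag)):
            patterns.append((t.tf_name, orientation, tag))
            rc = reverse_complement(tag)
            if rc != tag:
                patterns.append((t.tf_name, orientation, rc))

    n_total = n_dropped = n_scanned = 0
    hits: list[TagHit] = []
    for read in reads:
        n_total += 1
        if not read.cell_barcode or not read.umi:
            n_dropped += 1
            continue
        n_scanned += 1
        seen: dict[tuple[str, str, int], int] = {}
        for tf_name, orientation, pattern in patterns:
            for pos, mm in find_occurrences(read.sequence, pattern, max_mismatches):
                key = (tf_name, orientation, pos)
                if key not in seen or mm < seen[key]:
                    seen[key] = mm
        for (tf_name, orientation, pos), mm in sorted(seen.items()):
            hits.append(TagHit(read.read_id, tf_name, orientation, pos, mm))

    stats = {
        "n_reads_total": n_total,
        "n_reads_dropped_no_barcode_or_umi": n_dropped,
        "n_reads_scanned": n_scanned,
        "n_hits": len(hits),
    }
    if summary is not None:
        summary.update(stats)
    logger.info("scan_reads: %s", stats)
    return hits


def aggregate_umis(hits: Sequence[TagHit], reads: Iterable[TaggedRead]) -> list[UmiAssignment]:
    """Collapse read-level hits to one assignment per (cell barcode, UMI).

    The winning TF is the one supported by the most distinct reads in the
    molecule's read group; a read hitting several TFs' tags votes for each.
    A tie for the top count excludes the molecule (reason ``tf_tie``).
    """
    read_index: dict[str, TaggedRead] = {}
    group_totals: dict[tuple[str, str], int] = defaultdict(int)
    for r in reads:
        if not r.cell_barcode or not r.umi:
            continue
        read_index[r.read_id] = r
        group_totals[(r.cell_barcode, r.umi)] += 1

    support: dict[tuple[str, str], dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for h in hits:
        read = read_index.get(h.read_id)
        if read is None:
            continue
        support[(read.cell_barcode, read.umi)][h.tf_name].add(h.read_id)

    out: list[UmiAssignment] = []
    for (cb, umi), per_tf in sorted(support.items()):
        counts = {tf: len(ids) for tf, ids in per_tf.items()}
        top = max(counts.values())
        winners = sorted(tf for tf, c in counts.items() if c == top)
        if len(winners) > 1:
            out.append(UmiAssignment(cb, umi, "", top, group_totals[(cb, umi)],
                                     excluded=True, exclusion_reason="tf_tie"))
        else:
            out.append(UmiAssignment(cb, umi, winners[0], top, group_totals[(cb, umi)]))
    return out


def resolve_gene_conflicts(
    assignments: Sequence[UmiAssignment],
    reads: Iterable[TaggedRead],
) -> list[UmiAssignment]:
    """Apply the aligner-conflict exclusion rule at the transcript level.

    For each assignment, ``f`` is the fraction of the molecule's reads whose
    external gene annotation is present, not "NA", and different from the
    tag-derived TF. The molecule is excluded when f > 1/2 (strictly);
    molecules whose reads are all unannotated are retained.
    """
    groups: dict[tuple[str, str], list[TaggedRead]] = defaultdict(list)
    for r in reads:
        if not r.cell_barcode or not r.umi:
            continue
        groups[(r.cell_barcode, r.umi)].append(r)

    out: list[UmiAssignment] = []
    for a in assignments:
        if a.excluded:
            out.append(a)
            continue
        members = groups.get((a.cell_barcode, a.umi), [])
        conflicting = sum(
            1 for r in members
            if r.aligner_gene not in (None, "", NA_GENE) and r.aligner_gene != a.tf_name
        )
        if members and conflicting * 2 > len(members):
            out.append(replace(a, excluded=True, exclusion_reason="aligner_conflict"))
        else:
            out.append(a)
    return out


def umi_count_table(assignments: Sequence[UmiAssignment]) -> pd.DataFrame:
    """Cell × TF table of retained molecule (UMI) counts."""
    rows = [(a.cell_barcode, a.tf_name) for a in assignments if not a.excluded]
    if not rows:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(rows, columns=["cell_barcode", "tf_name"])
    table = df.value_counts().unstack(fill_value=0)
    table.columns.name = None
    table.index.name = "cell_barcode"
    return table.sort_index()


# ---------------------------------------------------------------------------
# read ingestion

def read_reads_tsv(path: str | Path) -> list[TaggedRead]:
    """Tabular reads: read_id, cell_barcode, umi, sequence[, aligner_gene]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    has_gene = "aligner_gene" in df.columns
    return [
        TaggedRead(
            read_id=r.read_id,
            cell_barcode=r.cell_barcode,
            umi=r.umi,
            sequence=r.sequence,
            aligner_gene=(r.aligner_gene or None) if has_gene else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_reads_tsv(reads: Sequence[TaggedRead], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "cell_barcode": r.cell_barcode,
                "umi": r.umi,
                "sequence": r.sequence,
                "aligner_gene": r.aligner_gene or "",
            }
            for r in reads
        ]
    ).to_csv(path, sep="\t", index=False)


def read_fastq_pair(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    umi_len: int = DEFAULT_UMI_LEN,
) -> list[TaggedRead]:
    """10x-style paired FASTQ: mate 1 = barcode + UMI, mate 2 = cDNA.

    Reads whose mate 1 is shorter than ``barcode_len + umi_len`` get empty
    barcode/UMI and are dropped downstream by :func:`scan_reads`.
    """
    import pysam

    out: list[TaggedRead] = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            s1 = e1.sequence or ""
            if len(s1) >= barcode_len + umi_len:
                cb = s1[:barcode_len]
                umi = s1[barcode_len:barcode_len + umi_len]
            else:
                cb = umi = ""
            out.append(TaggedRead(e2.name, cb, umi, (e2.sequence or "").upper()))
    return out


def write_assignments_tsv(assignments: Sequence[UmiAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cell_barcode": a.cell_barcode,
                "umi": a.umi,
                "tf_name": a.tf_name,
                "n_reads_supporting": a.n_reads_supporting,
                "n_reads_total": a.n_reads_total,
                "excluded": a.excluded,
                "exclusion_reason": a.exclusion_reason,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> list[UmiAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_barcode": str, "umi": str,
                                            "tf_name": str}, keep_default_na=False)
    return [
        UmiAssignment(
            cell_barcode=r.cell_barcode,
            umi=r.umi,
            tf_name=r.tf_name,
            n_reads_supporting=int(r.n_reads_supporting),
            n_reads_total=int(r.n_reads_total),
            excluded=str(r.excluded).lower() in ("true", "1"),
            exclusion_reason=r.exclusion_reason,
        )
        for r in df.itertuples(index=False)
    ]
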