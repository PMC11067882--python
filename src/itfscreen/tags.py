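"""Vector–ORF junction tag ("iTF tag") construction.

An induced transcription factor (iTF) is expressed from an integrated
inducible vector, so the ectopic transcript contains junctions between
vector sequence and the ORF that never occur in the endogenous transcript.
A short sequence spanning each junction therefore uniquely identifies the
ectopic transcript in sequencing reads.

Two tags are built per ORF:

* forward tag  — last ``vector_len`` nt of the vector sequence transcribed
  immediately upstream of the start codon, followed by the first
  ``core_len`` nt of the coding sequence (default 7 + 21 = 28 nt);
* reverse tag  — reverse complement of (last ``core_len`` nt of the CDS,
  including the stop codon, followed by the first ``vector_len`` nt of the
  downstream vector sequence).

A candidate tag that occurs verbatim in the reference genome (either
strand), or that equals another construct's tag, cannot be matched
unambiguously; such tags are lengthened on the ORF side one nucleotide at
a time until unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_CORE_LEN = 21
DEFAULT_VECTOR_LEN = 7
DEFAULT_MAX_TAG_LEN = 50
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class TagError(ValueError):
    """Base class for tag-construction failures."""


class CdsTooShort(TagError):
    """Coding sequence shorter than the requested tag core."""


class InvalidAlphabet(TagError):
    """Sequence contains characters outside A/C/G/T (ambiguity codes rejected)."""


class DuplicateName(TagError):
    """Two ORF records share a TF name."""


class UniquenessUnreachable(TagError):
    """No unique tag of length <= max_len exists for this construct."""


class TagWarning(UserWarning):
    """Non-fatal oddity in a construct (missing start/stop codon)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str) -> None:
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise InvalidAlphabet(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class OrfRecord:
    """One TF's coding sequence, start through stop codon, uppercase ACGT."""

    name: str
    cds: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper())
        _check_alphabet(self.cds, f"CDS of {self.name!r}")
        # start codon + enough for a forward core and a reverse core
        if len(self.cds) < 24:
            raise CdsTooShort(
                f"CDS of {self.name!r} is {len(self.cds)} nt; need >= 24"
            )
        if not self.cds.startswith("ATG"):
            warnings.warn(
                f"CDS of {self.name!r} does not begin with ATG", TagWarning,
                stacklevel=2,
            )
        if self.cds[-3:] not in STOP_CODONS:
            warnings.warn(
                f"CDS of {self.name!r} does not end with a stop codon",
                TagWarning, stacklevel=2,
            )


@dataclass(frozen=True)
class VectorContext:
    """Vector sequence transcribed around the insert.

    ``upstream`` ends immediately 5' of the inserted start codon;
    ``downstream`` begins immediately 3' of the stop codon.
    """

    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream", self.upstream.upper())
        object.__setattr__(self, "downstream", self.downstream.upper())
        _check_alphabet(self.upstream, "vector upstream context")
        _check_alphabet(self.downstream, "vector downstream context")


@dataclass(frozen=True)
class TagSpec:
    """Finalized forward/reverse tag pair for one construct."""

    tf_name: str
    forward_tag: str
    reverse_tag: str
    forward_len: int
    reverse_len: int
    core_len: int = DEFAULT_CORE_LEN
    vector_len: int = DEFAULT_VECTOR_LEN
    extended: bool = False


def build_forward_tag(
    orf: OrfRecord,
    vec: VectorContext,
    core_len: int = DEFAULT_CORE_LEN,
    vector_len: int = DEFAULT_VECTOR_LEN,
) -> str:
    """5' junction tag: last ``vector_len`` nt of upstream + first ``core_len`` nt of CDS."""
    if len(orf.cds) < core_len:
        raise CdsTooShort(
            f"CDS of {orf.name!r} is {len(orf.cds)} nt; forward core needs {core_len}"
        )
    if len(vec.upstream) < vector_len:
        raise TagError(
            f"vector upstream context is {len(vec.upstream)} nt; need {vector_len}"
        )
    prefix = vec.upstream[len(vec.upstream) - vector_len:] if vector_len else ""
    return prefix + orf.cds[:core_len]


def build_reverse_tag(
    orf: OrfRecord,
    vec: VectorContext,
    core_len: int = DEFAULT_CORE_LEN,
    vector_len: int = DEFAULT_VECTOR_LEN,
) -> str:
    """3' junction tag: revcomp(last ``core_len`` nt of CDS + first ``vector_len`` nt downstream)."""
    if len(orf.cds) < core_len:
        raise CdsTooShort(
            f"CDS of {orf.name!r} is {len(orf.cds)} nt; reverse core needs {core_len}"
        )
    if len(vec.downstream) < vector_len:
        raise TagError(
            f"vector downstream context is {len(vec.downstream)} nt; need {vector_len}"
        )
    return reverse_complement(orf.cds[len(orf.cds) - core_len:] + vec.downstream[:vector_len])


def build_tag(
    orf: OrfRecord,
    vec: VectorContext,
    core_len: int = DEFAULT_CORE_LEN,
    vector_len: int = DEFAULT_VECTOR_LEN,
) -> TagSpec:
    """Unextended forward/reverse tag pair for one ORF."""
    fwd = build_forward_tag(orf, vec, core_len, vector_len)
    rev = build_reverse_tag(orf, vec, core_len, vector_len)
    return TagSpec(
        tf_name=orf.name,
        forward_tag=fwd,
        reverse_tag=rev,
        forward_len=len(fwd),
        reverse_len=len(rev),
        core_len=core_len,
        vector_len=vector_len,
        extended=False,
    )


def occurs_in_genome(tag: str, genome: Mapping[str, str] | Sequence[str] | None) -> bool:
    """Exact full-length substring match against either strand of any genome sequence."""
    if genome is None:
        return False
    seqs = genome.values() if isinstance(genome, Mapping) else genome
    rc = reverse_complement(tag)
    for seq in seqs:
        s = seq.upper()
        if tag in s or rc in s:
            return True
    return False


def _forward_candidate(orf: OrfRecord, vec: VectorContext, core: int, vector_len: int) -> str | None:
    if core > len(orf.cds):
        return None
    return build_forward_tag(orf, vec, core, vector_len)


def _reverse_candidate(orf: OrfRecord, vec: VectorContext, core: int, vector_len: int) -> str | None:
    if core > len(orf.cds):
        return None
    return build_reverse_tag(orf, vec, core, vector_len)


def extend_tag_for_uniqueness(
    tag: TagSpec,
    orf: OrfRecord,
    vec: VectorContext,
    genome: Mapping[str, str] | Sequence[str] | None = None,
    all_tags: Iterable[TagSpec] = (),
    max_len: int = DEFAULT_MAX_TAG_LEN,
) -> TagSpec:
    """Lengthen tags that collide with the genome or with another construct's tags.

    The ORF-side core grows one nucleotide per iteration (the vector
    contribution is fixed), so the result is the shortest unique tag of the
    required form. Raises :class:`UniquenessUnreachable` when ``max_len`` is
    hit or the CDS is exhausted.
    """
    taken = set()
    for other in all_tags:
        if other.tf_name == tag.tf_name:
            continue
        taken.add(other.forward_tag)
        taken.add(other.reverse_tag)

    def is_unique(candidate: str, own_other: str) -> bool:
        return (
            candidate not in taken
            and candidate != own_other
            and not occurs_in_genome(candidate, genome)
        )

    fwd, rev = tag.forward_tag, tag.reverse_tag
    fwd_core, rev_core = tag.core_len, tag.core_len

    while not is_unique(fwd, rev):
        fwd_core += 1
        cand = _forward_candidate(orf, vec, fwd_core, tag.vector_len)
        if cand is None or len(cand) > max_len:
            raise UniquenessUnreachable(
                f"no unique forward tag of length <= {max_len} for {tag.tf_name!r}"
            )
        fwd = cand
    while not is_unique(rev, fwd):
        rev_core += 1
        cand = _reverse_candidate(orf, vec, rev_core, tag.vector_len)
        if cand is None or len(cand) > max_len:
            raise UniquenessUnreachable(
                f"no unique reverse tag of length <= {max_len} for {tag.tf_name!r}"
            )
        rev = cand

    extended = (fwd != tag.forward_tag) or (rev != tag.reverse_tag)
    if not extended:
        return tag
    return replace(
        tag,
        forward_tag=fwd,
        reverse_tag=rev,
        forward_len=len(fwd),
        reverse_len=len(rev),
        extended=True,
    )


def build_tag_table(
    orfs: Sequence[OrfRecord],
    vec: VectorContext,
    genome: Mapping[str, str] | Sequence[str] | None = None,
    core_len: int = DEFAULT_CORE_LEN,
    vector_len: int = DEFAULT_VECTOR_LEN,
    max_len: int = DEFAULT_MAX_TAG_LEN,
) -> list[TagSpec]:
    """Build one uniqueness-checked :class:`TagSpec` per ORF.

    ORFs are processed in input order; each tag is checked against the
    genome and against every previously finalized tag, so a later construct
    colliding with an earlier one is the one that gets extended.
    """
    names = [o.name for o in orfs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DuplicateName(f"duplicate TF names: {sorted(dupes)}")

    table: list[TagSpec] = []
    for orf in orfs:
        spec = build_tag(orf, vec, core_len, vector_len)
        spec = extend_tag_for_uniqueness(
            spec, orf, vec, genome=genome, all_tags=table, max_len=max_len
        )
        table.append(spec)
    return table


_TAG_COLUMNS = [
    "tf_name", "forward_tag", "reverse_tag", "forward_len", "reverse_len",
    "core_len", "vector_len", "extended",
]


def tag_table_to_frame(table: Sequence[TagSpec]) -> pd.DataFrame:
    """Tag table as a DataFrame with one row per construct."""
    return pd.DataFrame([{c: getattr(t, c) for c in _TAG_COLUMNS} for t in table],
                        columns=_TAG_COLUMNS)


def write_tag_table(table: Sequence[TagSpec], path: str | Path) -> None:
    tag_table_to_frame(table).to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path) -> list[TagSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        TagSpec(
            tf_name=str(r.tf_name),
            forward_tag=str(r.forward_tag),
            reverse_tag=str(r.reverse_tag),
            forward_len=int(r.forward_len),
            reverse_len=int(r.reverse_len),
            core_len=int(r.core_len),
            vector_len=int(r.vector_len),
            extended=bool(r.extended),
        )
        for r in df.itertuples(index=False)
    ]
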