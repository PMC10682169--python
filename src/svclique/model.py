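"""Core domain types shared across the calling pipeline.

Coordinates are 0-based, half-open throughout the library; conversion to
1-based happens only in the VCF writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

SVTYPES = ("DEL", "INS", "DUP", "INV", "TRA")


class ContractViolation(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class AlignedSegmentView:
    """Orientation-normalized view of one alignment record.

    ``query_start``/``query_end`` are in original read coordinates (i.e.
    measured on the sequenced molecule, independent of mapping strand) so
    that segments of a split read can be ordered along the read.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    cigar: tuple  # ((op, length), ...) with pysam op codes
    is_primary: bool
    is_supplementary: bool
    query_start: int
    query_end: int
    mapq: int

    def __post_init__(self):
        if not self.ref_start < self.ref_end:
            raise ContractViolation(
                f"segment of read {self.read_id!r}: ref_start must be < ref_end"
            )
        if not self.query_start < self.query_end:
            raise ContractViolation(
                f"segment of read {self.read_id!r}: query_start must be < query_end"
            )


@dataclass(frozen=True)
class SvSignature:
    """One SV-supporting observation extracted from one read."""

    svtype: str
    chrom: str
    start: int
    end: int
    read_id: str
    origin: str  # "gap" or "split"
    length: int = 0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    strand_pair: Optional[str] = None

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ContractViolation(f"unknown svtype {self.svtype!r}")
        if self.start > self.end:
            raise ContractViolation(
                f"signature {self.svtype} on read {self.read_id!r}: start > end"
            )
        if (self.svtype == "TRA") != (self.chrom2 is not None):
            raise ContractViolation("chrom2 is set iff svtype is TRA")
        if self.svtype == "TRA" and self.chrom2 == self.chrom:
            raise ContractViolation("TRA requires chrom2 != chrom")

    @property
    def interval(self) -> tuple:
        """Interval used for overlap computations.

        Insertions occupy no reference span, so they are compared on the
        pseudo-interval [start, start+length).
        """
        if self.svtype == "INS":
            return (self.start, self.start + self.length)
        return (self.start, self.end)

    def group_key(self) -> tuple:
        """(svtype, chromosome-group) key under which signatures are clustered."""
        if self.svtype == "TRA":
            pair = tuple(sorted((self.chrom, self.chrom2)))
            return ("TRA", pair, self.strand_pair)
        return (self.svtype, self.chrom)


class SignatureSet:
    """Signatures grouped by (svtype, chromosome) / chromosome pair for TRA.

    Within each group, signatures are kept sorted by (start, read_id) so the
    downstream clustering is deterministic regardless of extraction order or
    thread count.
    """

    def __init__(self, sample: str = "sample"):
        self.sample = sample
        self._groups: dict = {}

    def add(self, sig: SvSignature) -> None:
        self._groups.setdefault(sig.group_key(), []).append(sig)

    def extend(self, sigs: Iterable[SvSignature]) -> None:
        for s in sigs:
            self.add(s)

    def finalize(self) -> "SignatureSet":
        """Deduplicate and sort every group; returns self."""
        for key, sigs in self._groups.items():
            seen = {}
            for s in sigs:
                dedup = (s.read_id, s.svtype, s.start, s.end, s.chrom2, s.pos2)
                if dedup not in seen:
                    seen[dedup] = s
            self._groups[key] = sorted(
                seen.values(), key=lambda s: (s.start, s.end, s.read_id)
            )
        return self

    def groups(self):
        for key in sorted(self._groups, key=repr):
            yield key, self._groups[key]

    def group(self, key) -> list:
        return self._groups.get(key, [])

    def all_signatures(self) -> list:
        out = []
        for _, sigs in self.groups():
            out.extend(sigs)
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._groups.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, SignatureSet) and dict(self.groups()) == dict(
            other.groups()
        )


@dataclass
class SvCluster:
    """A group of signatures attributed to one SV event."""

    svtype: str
    chrom: str
    start: int
    end: int
    length: int
    support: int
    read_ids: frozenset
    cohesion: float
    start_mean: float
    start_mode: int
    start_sd: float
    end_mean: float
    end_mode: int
    end_sd: float
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    strand_pair: Optional[str] = None
    members: tuple = ()

    def as_signature(self) -> SvSignature:
        """Median representation of the cluster, usable in NRO computations."""
        return SvSignature(
            svtype=self.svtype,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            length=self.length,
            read_id=f"cluster:{self.chrom}:{self.start}",
            origin="split",
            chrom2=self.chrom2,
            pos2=self.pos2,
            strand_pair=self.strand_pair,
        )


@dataclass
class GenotypeCall:
    gt: str  # "0/0", "0/1", "1/1" or "./."
    v: int
    n: int
    gq: int
    posteriors: tuple

    def __post_init__(self):
        if self.gt != "./." and not 0 <= self.v <= self.n:
            raise ContractViolation("genotype call requires 0 <= v <= n")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for the somatic Fisher test.

    Rows are samples (test, control); columns are variant-supporting vs
    reference-supporting reads.
    """

    n_vrt: int
    n_rrt: int
    n_vrc: int
    n_rrc: int

    def __post_init__(self):
        if min(self.n_vrt, self.n_rrt, self.n_vrc, self.n_rrc) < 0:
            raise ContractViolation("contingency counts must be non-negative")


@dataclass
class SomaticCall:
    cluster: SvCluster
    table: ContingencyTable
    p_value: float
    is_somatic: bool
    genotype: Optional[GenotypeCall] = None


@dataclass(frozen=True)
class TruthRecord:
    """A simulated SV with exact breakpoints, used by the evaluation module."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotype: str
    somatic: bool
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
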