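"""Reading annotated mitogenomes and extracting large unassigned regions (LURs).

The LUR of a mitochondrial genome is the stretch of DNA not covered by any
protein-coding or ribosomal-RNA gene; in bivalves it typically houses the
control region and, in species with doubly uniparental inheritance (DUI),
the putative sperm transmission element. Boundary rules implemented here:

* only ``protein_coding`` and ``rRNA`` features bound an unassigned region;
* tRNAs are neither masked nor allowed to split a region — a gap containing
  tRNAs is reported as one contiguous LUR spanning them;
* features of uncertain status (DUI ORFs annotated inconsistently, e.g. as a
  bare ``misc_feature``) are classified ``orf_uncertain`` / ``other`` and do
  not bound LURs;
* on circular genomes an unassigned region may wrap the replication origin
  and is returned as a single wrapped interval.

Coordinates are 0-based half-open throughout; a wrapped interval has
``end <= start`` and is understood to run ``start .. genome_length`` then
``0 .. end``. Written reports use 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("protein_coding", "rRNA", "tRNA", "orf_uncertain", "other")
#: feature kinds that delimit unassigned regions
BOUNDARY_KINDS = frozenset({"protein_coding", "rRNA"})

_GENBANK_KIND = {
    "CDS": "protein_coding",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}
_SKIP_TYPES = {"source", "gene"}


@dataclass
class Feature:
    """One annotated feature on a genome.

    ``interval`` is 0-based half-open and may wrap the origin
    (``end <= start``) on circular genomes.
    """

    kind: str
    strand: str
    interval: tuple[int, int]
    name: str = ""

    def length(self, genome_length: int) -> int:
        s, e = self.interval
        return e - s if e > s else genome_length - s + e


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    circular: bool
    features: list[Feature] = field(default_factory=list)
    mitotype_label: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LUR:
    """A large unassigned region: an interval uncovered by boundary features."""

    genome_id: str
    interval: tuple[int, int]
    sequence: str
    strand_basis: str = "forward"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def freqs(self) -> tuple[float, float, float, float]:
        """Base frequencies (T, C, G, A) of the LUR, ignoring ambiguous bases."""
        return base_frequencies(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes handled)."""
    return str(Seq(seq).reverse_complement())


def base_frequencies(seq: str) -> tuple[float, float, float, float]:
    """Proportions of (T, C, G, A) over the unambiguous bases of ``seq``.

    Ambiguous bases (N etc.) are excluded from both numerator and
    denominator. Raises ``ValueError`` when no unambiguous base is present.
    """
    s = seq.upper()
    counts = [s.count(b) for b in "TCGA"]
    total = sum(counts)
    if total == 0:
        raise ValueError("cannot compute base frequencies: no unambiguous bases")
    return tuple(c / total for c in counts)  # type: ignore[return-value]


def interval_length(interval: tuple[int, int], genome_length: int) -> int:
    s, e = interval
    return e - s if e > s else genome_length - s + e


def extract_region(genome: GenomeRecord, interval: tuple[int, int], strand: str = "+") -> str:
    """Slice ``interval`` out of the genome; wrap allowed only when circular.

    On strand ``-`` the reverse complement of the forward slice is returned.
    Wrapped intervals concatenate the tail of the sequence with its head.
    """
    s, e = interval
    n = len(genome)
    if not (0 <= s < n and 0 <= e <= n):
        raise ValueError(f"interval {interval} outside genome of length {n}")
    if e > s:
        region = genome.sequence[s:e]
    else:
        if not genome.circular:
            raise ValueError(f"wrapped interval {interval} on linear record {genome.id}")
        region = genome.sequence[s:] + genome.sequence[:e]
    if strand == "-":
        region = reverse_complement(region)
    return region


_MITOTYPE_PATTERNS = [
    (re.compile(r"recently\s+masculini[sz]ed|\bRM[- ]?type|\bRM\b", re.I), "RM"),
    (re.compile(r"hermaphrodit|\bH[- ]?type\b", re.I), "H"),
    (re.compile(r"\bF[- ]?type\b|female[- ]transmitted|\bfemale\b", re.I), "F"),
    (re.compile(r"\bM[- ]?type\b|male[- ]transmitted|\bmale\b", re.I), "M"),
]


def infer_mitotype(description: str) -> str:
    """Best-effort mitotype (F/M/RM/H) from a sequence description string."""
    for pat, label in _MITOTYPE_PATTERNS:
        if pat.search(description):
            return label
    return "unknown"


def _location_to_interval(loc, genome_length: int) -> tuple[int, int]:
    """Convert a Biopython location to a possibly wrapped (start, end)."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning annotation: [x, L) + [0, y)
        if (
            len(parts) == 2
            and int(parts[1].end) == genome_length
            and int(parts[0].start) == 0
        ):
            return int(parts[1].start), int(parts[0].end)
        return int(parts[0].start), int(parts[-1].end)
    return int(loc.start), int(loc.end)


def read_genome(
    path: str | Path,
    fmt: str = "genbank",
    overrides: dict[int, str] | None = None,
) -> GenomeRecord:
    """Read one annotated genome from a GenBank flat file.

    ``overrides`` maps feature index -> new kind and reclassifies features
    after parsing (the mechanism for flagging inconsistently annotated DUI
    ORFs as ``orf_uncertain`` so they do not bound LURs).
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), fmt)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(rec.seq) == 0:
        raise ValueError(f"record {rec.id} in {path} has an empty sequence")
    topology = rec.annotations.get("topology", "linear")
    features: list[Feature] = []
    for feat in rec.features:
        if feat.type in _SKIP_TYPES:
            continue
        kind = _GENBANK_KIND.get(feat.type, "other")
        strand = "-" if feat.location.strand == -1 else "+"
        interval = _location_to_interval(feat.location, len(rec.seq))
        name = (
            feat.qualifiers.get("gene", [""])[0]
            or feat.qualifiers.get("product", [""])[0]
            or feat.type
        )
        features.append(Feature(kind=kind, strand=strand, interval=interval, name=name))
    if overrides:
        for idx, new_kind in overrides.items():
            if new_kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {new_kind!r}")
            features[idx].kind = new_kind
    return GenomeRecord(
        id=rec.id or path.stem,
        sequence=str(rec.seq),
        circular=topology == "circular",
        features=features,
        mitotype_label=infer_mitotype(rec.description or ""),
        description=rec.description or "",
    )


def read_override_table(path: str | Path) -> dict[str, dict[int, str]]:
    """Read an annotation-override TSV: genome_id, feature_index, new_kind."""
    out: dict[str, dict[int, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gid, idx, kind = row[0], int(row[1]), row[2]
            out.setdefault(gid, {})[idx] = kind
    return out


def extract_lurs(genome: GenomeRecord, min_length: int = 100) -> list[LUR]:
    """Maximal intervals not covered by protein-coding/rRNA features.

    tRNA, ``orf_uncertain`` and ``other`` features neither bound nor mask a
    region. Regions shorter than ``min_length`` are dropped, except that the
    single longest region is always returned. Result is sorted by length,
    longest first; on circular genomes one interval may wrap the origin.
    """
    n = len(genome)
    covered = np.zeros(n, dtype=bool)
    has_boundary = False
    for feat in genome.features:
        if feat.kind not in BOUNDARY_KINDS:
            continue
        has_boundary = True
        s, e = feat.interval
        if e > s:
            covered[s:e] = True
        else:
            if not genome.circular:
                raise ValueError(f"wrapped feature on linear record {genome.id}")
            covered[s:] = True
            covered[:e] = True
    if not has_boundary:
        raise ValueError(f"cannot define LURs for {genome.id}: no protein-coding or rRNA feature")

    gaps = _uncovered_intervals(covered, circular=genome.circular)
    lurs = [
        LUR(genome_id=genome.id, interval=iv, sequence=extract_region(genome, iv))
        for iv in gaps
    ]
    lurs.sort(key=lambda l: (-l.length, l.interval[0]))
    if not lurs:
        return []
    kept = [l for l in lurs if l.length >= min_length]
    if not kept:
        kept = [lurs[0]]
    return kept


def _uncovered_intervals(covered: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    n = covered.size
    if not covered.any():
        return [(0, n)] if not circular else [(0, n)]
    uncov = ~covered
    if not uncov.any():
        return []
    # run boundaries on the linear axis
    diff = np.diff(uncov.astype(np.int8))
    starts = list((np.nonzero(diff == 1)[0] + 1))
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if uncov[0]:
        starts.insert(0, 0)
    if uncov[-1]:
        ends.append(n)
    intervals = list(zip(starts, ends))
    if circular and len(intervals) >= 2 and uncov[0] and uncov[-1]:
        # merge the run touching the end with the run touching the start
        first = intervals.pop(0)
        last = intervals.pop()
        intervals.append((last[0], first[1]))  # wrapped
    return [(int(s), int(e)) for s, e in intervals]


def write_lur_fasta(lurs: Iterable[LUR], path: str | Path) -> None:
    """Write LURs as FASTA with headers ``genome_id|start-end|strand``."""
    records = []
    for lur in lurs:
        s, e = lur.interval
        header = f"{lur.genome_id}|{s + 1}-{e}|{'+' if lur.strand_basis == 'forward' else '-'}"
        records.append(SeqRecord(Seq(lur.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_lur_table(lurs: Sequence[LUR], path: str | Path) -> None:
    """LUR summary TSV: id, 1-based start, end, L, and pi(T,C,G,A)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "start", "end", "length", "pi_T", "pi_C", "pi_G", "pi_A"])
        for lur in lurs:
            s, e = lur.interval
            pt, pc, pg, pa = lur.freqs
            w.writerow(
                [lur.genome_id, s + 1, e, lur.length]
                + [f"{x:.4f}" for x in (pt, pc, pg, pa)]
            )


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (circular topology kept)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace("|", "_"),
        description=genome.description or f"synthetic mitogenome {genome.id}",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    n = len(genome)
    kind_to_type = {
        "protein_coding": "CDS",
        "rRNA": "rRNA",
        "tRNA": "tRNA",
        # uncertain DUI ORFs mirror the real-world case of an F-ORF annotated
        # as a bare miscellaneous feature rather than a gene
        "orf_uncertain": "misc_feature",
        "other": "misc_feature",
    }
    for feat in genome.features:
        s, e = feat.interval
        strand = -1 if feat.strand == "-" else 1
        if e > s:
            loc = SimpleLocation(s, e, strand=strand)
        else:
            loc = CompoundLocation(
                [SimpleLocation(s, n, strand=strand), SimpleLocation(0, e, strand=strand)]
            )
        qualifiers = {}
        if feat.name:
            qualifiers["gene" if feat.kind != "other" else "note"] = [feat.name]
        rec.features.append(
            SeqFeature(loc, type=kind_to_type.get(feat.kind, "misc_feature"), qualifiers=qualifiers)
        )
    SeqIO.write([rec], str(path), "genbank")
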