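"""Annotation parsing, strand-aware 5'-shift calling and matrix building.

Coordinates are 1-based inclusive throughout (GFF3 convention). On the
minus strand the 5' end of a mature miRNA is its *higher* genomic
coordinate, so the signed shift is computed from record ends there.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import IsomiRKey, reverse_complement, to_rna

log = logging.getLogger(__name__)


class GFF3ParseError(ValueError):
    pass


class ShiftAssignmentError(ValueError):
    """Raised when an isoform row cannot be assigned to its archetype locus."""


@dataclass(frozen=True)
class MatureRecord:
    accession: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    hairpin_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.accession}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.accession}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class IsoformRow:
    accession: str
    chrom: str
    start: int
    end: int
    strand: str
    read_count: int
    rpm: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if self.start > self.end:
            raise ValueError("start > end")


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def parse_gff3(path: str | Path) -> list[MatureRecord]:
    """Parse a miRBase-dialect GFF3, returning only mature ("miRNA") records.

    Hairpin rows ("miRNA_primary_transcript") are used to resolve the
    ``Derives_from`` parent of each mature record. A mature row without a
    known parent is retained with a null hairpin id and a warning.
    """
    hairpins: set[str] = set()
    matures: list[MatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype == "miRNA_primary_transcript":
                hairpins.add(_parse_attributes(attrs).get("ID", ""))
            elif ftype == "miRNA":
                a = _parse_attributes(attrs)
                acc = a.get("ID") or a.get("Name")
                if acc is None:
                    raise GFF3ParseError(f"{path}:{lineno}: miRNA row without ID")
                parent = a.get("Derives_from")
                if parent is not None and parent not in hairpins:
                    log.warning("%s:%d: mature %s has unknown parent %s", path, lineno, acc, parent)
                matures.append(
                    MatureRecord(
                        accession=acc,
                        name=a.get("Name", acc),
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        hairpin_id=parent,
                    )
                )
    return matures


_REGION_RE = re.compile(
    r"^(?:(?P<assembly>[A-Za-z0-9_.]+):)?(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$"
)


def parse_region(region: str) -> tuple[str, int, int, str]:
    """Parse a GDC-style region string ``[assembly:]chrom:start-end:strand``."""
    m = _REGION_RE.match(region.strip())
    if m is None:
        raise ValueError(f"cannot parse region string: {region!r}")
    return m.group("chrom"), int(m.group("start")), int(m.group("end")), m.group("strand")


def compute_shift(archetype: MatureRecord, row: IsoformRow) -> int:
    """Signed 5' shift of ``row`` relative to its archetype.

    Plus strand: ``row.start - archetype.start``. Minus strand:
    ``archetype.end - row.end``. Positive values mean the isoform 5' start
    lies downstream of the archetype 5' start on the mature strand.
    """
    if row.accession != archetype.accession:
        raise ShiftAssignmentError(
            f"accession mismatch: {row.accession} vs {archetype.accession}"
        )
    if row.chrom != archetype.chrom or row.strand != archetype.strand:
        raise ShiftAssignmentError(
            f"{row.accession}: row on {row.chrom}{row.strand}, archetype on "
            f"{archetype.chrom}{archetype.strand}"
        )
    if archetype.strand == "+":
        return row.start - archetype.start
    return archetype.end - row.end


def read_isoform_table(path: str | Path) -> list[IsoformRow]:
    """Read a GDC-style ``isoforms.quantification.txt`` table."""
    df = pd.read_csv(path, sep="\t")
    required = {"miRNA_ID", "isoform_coords", "read_count", "reads_per_million_miRNA_mapped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        chrom, start, end, strand = parse_region(rec.isoform_coords)
        rows.append(
            IsoformRow(
                accession=rec.miRNA_ID,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                read_count=int(rec.read_count),
                rpm=float(rec.reads_per_million_miRNA_mapped),
            )
        )
    return rows


@dataclass
class IsomiRMatrix:
    """Samples x isomiRs expression with aligned count and RPM grids.

    Grids are stored features-in-rows (index = isomiR labels, columns =
    sample ids). ``max3p`` records, per key, the furthest 3' genomic
    extent observed anywhere in the dataset (max end on '+', min start
    on '-').
    """

    counts: pd.DataFrame
    rpm: pd.DataFrame
    max3p: dict[str, int]
    sample_groups: pd.Series  # sample id -> "tumor" | "normal"
    skip_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.shape != self.rpm.shape:
            raise ValueError("count and RPM grids must have identical shapes")
        if not self.counts.index.equals(self.rpm.index) or not self.counts.columns.equals(
            self.rpm.columns
        ):
            raise ValueError("count and RPM grids must be aligned")

    @property
    def keys(self) -> list[IsomiRKey]:
        return [IsomiRKey.parse(lbl) for lbl in self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _index_annotation(records: Sequence[MatureRecord]) -> dict[str, list[MatureRecord]]:
    idx: dict[str, list[MatureRecord]] = {}
    for r in records:
        idx.setdefault(r.accession, []).append(r)
    return idx


def _match_locus(row: IsoformRow, loci: list[MatureRecord]) -> MatureRecord | None:
    """Pick the annotated locus matching a row's chrom/strand with overlap.

    Multi-locus accessions resolve to the overlapping locus; ambiguity or
    no match yields None (row skipped by the caller).
    """
    candidates = [
        r
        for r in loci
        if r.chrom == row.chrom and r.strand == row.strand and row.start <= r.end + 30 and row.end >= r.start - 30
    ]
    if len(candidates) == 1:
        return candidates[0]
    return None


def build_matrix(
    rows_per_sample: Mapping[str, Sequence[IsoformRow]],
    annotation: Sequence[MatureRecord],
    sample_groups: Mapping[str, str] | None = None,
) -> IsomiRMatrix:
    """Aggregate isoform rows into an isomiR expression matrix.

    Rows sharing an (accession, shift) key within a sample are summed over
    read_count and RPM regardless of their 3' ends; total read mass is
    conserved. Rows whose accession is absent from the annotation, or that
    sit on the wrong chromosome/strand, are skipped and tallied in
    ``skip_report``.
    """
    idx = _index_annotation(annotation)
    counts: dict[str, dict[str, float]] = {}
    rpms: dict[str, dict[str, float]] = {}
    max3p: dict[str, int] = {}
    skips: list[dict] = []

    for sample, rows in rows_per_sample.items():
        for row in rows:
            loci = idx.get(row.accession)
            if not loci:
                skips.append({"sample": sample, "accession": row.accession, "reason": "unknown_accession"})
                continue
            locus = _match_locus(row, loci)
            if locus is None:
                skips.append({"sample": sample, "accession": row.accession, "reason": "locus_mismatch"})
                continue
            shift = compute_shift(locus, row)
            label = IsomiRKey(row.accession, shift).label
            counts.setdefault(label, {}).setdefault(sample, 0)
            rpms.setdefault(label, {}).setdefault(sample, 0.0)
            counts[label][sample] += row.read_count
            rpms[label][sample] += row.rpm
            extent = row.end if locus.strand == "+" else row.start
            if label not in max3p:
                max3p[label] = extent
            elif locus.strand == "+":
                max3p[label] = max(max3p[label], extent)
            else:
                max3p[label] = min(max3p[label], extent)

    samples = list(rows_per_sample)
    labels = sorted(counts, key=lambda l: (IsomiRKey.parse(l).accession, IsomiRKey.parse(l).shift))
    cdf = pd.DataFrame(0.0, index=labels, columns=samples)
    rdf = pd.DataFrame(0.0, index=labels, columns=samples)
    for label in labels:
        for sample, v in counts[label].items():
            cdf.at[label, sample] = v
        for sample, v in rpms[label].items():
            rdf.at[label, sample] = v

    groups = pd.Series(
        {s: (sample_groups or {}).get(s, "tumor") for s in samples}, name="group"
    )
    report = pd.DataFrame(skips, columns=["sample", "accession", "reason"])
    return IsomiRMatrix(counts=cdf, rpm=rdf, max3p=max3p, sample_groups=groups, skip_report=report)


def isomir_sequence(
    key: IsomiRKey,
    annotation: Sequence[MatureRecord],
    sequences: Mapping[str, str],
    max3p: Mapping[str, int],
) -> str:
    """Reconstruct the isomiR RNA sequence for ``key``.

    The sequence runs from the shifted 5' start to the furthest 3' extent
    observed for this key in the dataset; minus-strand keys are reverse
    complemented into mature orientation.
    """
    if key.label not in max3p:
        raise KeyError(f"key never observed in the dataset: {key.label}")
    loci = [r for r in annotation if r.accession == key.accession]
    if not loci:
        raise KeyError(f"accession not annotated: {key.accession}")
    arch = loci[0]
    chrom_seq = sequences[arch.chrom]
    extent = max3p[key.label]
    if arch.strand == "+":
        start = arch.start + key.shift
        return to_rna(chrom_seq[start - 1 : extent])
    five = arch.end - key.shift
    return reverse_complement(chrom_seq[extent - 1 : five])


def seed_of(sequence: str) -> str:
    """Seed region: positions 2-8 (1-based) of the 5' sequence, 7 nt."""
    if len(sequence) < 8:
        raise ValueError(f"sequence too short for a seed (need >= 8 nt): {len(sequence)}")
    return sequence[1:8]


def filter_samples(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the file-level cleaning rules to a download manifest.

    Expects columns ``file_id``, ``participant``, ``sample_type`` and
    boolean ``has_annotation``. Rules, in order: drop annotation-flagged
    files; keep one file per (participant, sample_type), first by sorted
    file id; drop "Recurrent Solid Tumor" files. Returns the cleaned
    manifest and per-rule removal counts.
    """
    required = {"file_id", "participant", "sample_type", "has_annotation"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    report: dict[str, int] = {}

    kept = manifest[~manifest["has_annotation"].astype(bool)]
    report["annotation"] = len(manifest) - len(kept)

    kept = kept.sort_values("file_id", kind="stable")
    dedup = kept.drop_duplicates(subset=["participant", "sample_type"], keep="first")
    report["duplicate_participant"] = len(kept) - len(dedup)

    final = dedup[dedup["sample_type"] != "Recurrent Solid Tumor"]
    report["recurrent_tumor"] = len(dedup) - len(final)

    return final.reset_index(drop=True), report
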