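"""Reading pileup text and VCF; reading/writing the per-position score table.

Only parsing and filtering happens here. Coordinates are 1-based throughout
(the native convention of both pileup and VCF). The pileup dialect is the
6-column samtools mpileup text format: chrom, pos, ref, depth, base string,
base-quality string (Phred+33).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

SCORE_TABLE_COLUMNS = (
    "chrom",
    "pos",
    "n_informative",
    "rdab1",
    "rdab2",
    "rdab3",
    "lr_response",
    "abb",
    "confidence",
)

_BASES = frozenset("ACGT")


class PileupParseError(ValueError):
    """Malformed pileup record (column count or base/quality mismatch)."""


class VcfFormatError(ValueError):
    """VCF lacking required fields (e.g. GT)."""


@dataclass(frozen=True)
class SiteObservation:
    """One sample's read evidence at one genomic position.

    ``depth_informative`` and ``alt_count`` count only reads whose base
    quality passed the parse-time filter; ``alt_count`` is for the single
    most frequent non-reference base (ties broken lexicographically).
    """

    chrom: str
    pos: int
    ref_base: str
    depth_informative: int
    alt_count: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not 0 <= self.alt_count <= self.depth_informative:
            raise ValueError("need 0 <= alt_count <= depth_informative")

    @property
    def ab(self) -> float:
        """Allele balance: alt_count / depth_informative (0 when uncovered)."""
        if self.depth_informative == 0:
            return 0.0
        return self.alt_count / self.depth_informative


@dataclass
class ScoreTableRow:
    """One row of the per-position callability score table."""

    chrom: str
    pos: int
    n_informative: int
    rdab1: float
    rdab2: float
    rdab3: float
    lr_response: float
    abb: float
    confidence: str


def parse_pileup_line(
    line: str, min_baseq: int = 20, line_number: int | None = None
) -> SiteObservation:
    """Parse one mpileup text record, dropping reads below ``min_baseq``.

    Pileup markup is consumed: ``^`` plus its mapping-quality byte, ``$``,
    indel spans ``+N.../-N...``, and deletion/refskip placeholders
    (``*``, ``#``, ``<``, ``>``) which consume a quality char but are not
    base calls. ``.``/``,`` count as reference; ``N`` is ignored as a call.
    """
    where = f" (line {line_number})" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        # samtools writes "chrom pos ref 0 * *" through tabs as well; some
        # writers collapse whitespace, accept that too
        fields = line.split()
    if len(fields) < 6:
        if len(fields) == 4 and fields[3] == "0":
            return SiteObservation(fields[0], int(fields[1]), fields[2].upper(), 0, 0)
        raise PileupParseError(f"expected 6 columns, got {len(fields)}{where}")
    chrom, pos_s, ref, _depth_s, bases, quals = fields[:6]
    ref = ref.upper()
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(f"non-integer position {pos_s!r}{where}") from None

    if bases == "*" and quals == "*":  # zero-coverage placeholder
        return SiteObservation(chrom, pos, ref, 0, 0)

    calls: list[str | None] = []  # one entry per read (consumes one qual)
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping-quality byte, no quality consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"indel span without length at offset {i}{where}")
            span = int(bases[i + 1 : j])
            i = j + span  # the inserted/deleted sequence, no quality consumed
            continue
        if c in ".,":
            calls.append("REF")
        elif c.upper() in _BASES:
            calls.append(c.upper())
        elif c in "*#<>Nn":
            calls.append(None)  # placeholder/ambiguous: consumes qual, no call
        else:
            raise PileupParseError(f"unexpected pileup character {c!r}{where}")
        i += 1

    if len(calls) != len(quals):
        raise PileupParseError(
            f"base string decodes to {len(calls)} reads but quality string has "
            f"{len(quals)} characters{where}"
        )

    depth = 0
    alt_counts: dict[str, int] = {}
    for call, qc in zip(calls, quals):
        if call is None:
            continue
        if ord(qc) - 33 < min_baseq:
            continue
        depth += 1
        if call != "REF" and call != ref:
            alt_counts[call] = alt_counts.get(call, 0) + 1
    alt = 0
    if alt_counts:
        # most frequent non-reference base; ties break lexicographically
        alt = max(alt_counts.values())
        best = min(b for b, c in alt_counts.items() if c == alt)
        alt = alt_counts[best]
    return SiteObservation(chrom, pos, ref, depth, alt)


def read_pileup(path, min_baseq: int = 20) -> Iterator[SiteObservation]:
    """Stream SiteObservations from an mpileup text file."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(line, min_baseq=min_baseq, line_number=ln)


@dataclass(frozen=True)
class VcfSiteRow:
    """One biallelic SNV row; multiallelic records are split per ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: tuple  # per-sample labels: hom_ref | het | hom_alt | missing


def _gt_label(gt, allele_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    dosage = sum(1 for a in gt if a == allele_index)
    ploidy = sum(1 for a in gt if a is not None)
    if dosage == 0:
        return "hom_ref"
    if dosage >= ploidy:
        return "hom_alt"
    return "het"


def read_vcf_sites(path) -> list[VcfSiteRow]:
    """Biallelic SNV rows from a VCF 4.x file with GT fields.

    Multiallelic records are split into one row per ALT allele; non-SNV
    alleles are skipped (count logged).
    """
    vcf = pysam.VariantFile(str(path))
    if "GT" not in vcf.header.formats:
        raise VcfFormatError("VCF has no GT FORMAT field")
    rows: list[VcfSiteRow] = []
    skipped = 0
    for rec in vcf:
        for ai, alt in enumerate(rec.alts or (), start=1):
            if len(rec.ref) != 1 or alt is None or len(alt) != 1 or alt not in _BASES:
                skipped += 1
                continue
            gts = tuple(
                _gt_label(rec.samples[s].get("GT"), ai) for s in rec.samples
            )
            rows.append(VcfSiteRow(rec.chrom, rec.pos, rec.ref, alt, gts))
    if skipped:
        logger.info("skipped %d non-SNV ALT alleles", skipped)
    return rows


def write_score_table(rows: Iterable[ScoreTableRow], dest) -> None:
    """Write the tab-separated score table (floats at 6 decimals).

    Rows must arrive sorted by (chrom, pos); unsorted input is an error so
    the writer can stream without buffering.
    """
    seen_chroms: list[str] = []
    last_pos = None
    with open(dest, "w") as fh:
        fh.write("\t".join(SCORE_TABLE_COLUMNS) + "\n")
        for row in rows:
            if not seen_chroms or row.chrom != seen_chroms[-1]:
                if row.chrom in seen_chroms:
                    raise ValueError(f"rows not sorted: chromosome {row.chrom} revisited")
                seen_chroms.append(row.chrom)
                last_pos = None
            if last_pos is not None and row.pos < last_pos:
                raise ValueError(f"rows not sorted at {row.chrom}:{row.pos}")
            last_pos = row.pos
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.n_informative}\t"
                f"{row.rdab1:.6f}\t{row.rdab2:.6f}\t{row.rdab3:.6f}\t"
                f"{row.lr_response:.6f}\t{row.abb:.6f}\t{row.confidence}\n"
            )


def read_score_table(path) -> list[ScoreTableRow]:
    """Read a score table written by :func:`write_score_table`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SCORE_TABLE_COLUMNS:
            raise ValueError(f"unexpected score-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                ScoreTableRow(
                    f[0], int(f[1]), int(f[2]), float(f[3]), float(f[4]),
                    float(f[5]), float(f[6]), float(f[7]), f[8],
                )
            )
    return rows


def load_abb_scores(path) -> dict[tuple[str, int], float]:
    """(chrom, pos) -> ABB score lookup from a score table file."""
    return {(r.chrom, r.pos): r.abb for r in read_score_table(path)}
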