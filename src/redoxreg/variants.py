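"""Variant screening and frameshift-consequence prediction.

The genome-comparison logic used to pin down a spontaneous mutation:
filter calls by read coverage and alternate-allele frequency, take the
set difference between the mutant and wild-type call sets, and predict
the protein consequence of an indel in a CDS — including the
position-ambiguous but sequence-identical case of a single-base deletion
inside a homopolymer run (e.g. one G out of seven consecutive G).

Filter semantics: KEEP a call iff coverage >= min_coverage (default 10)
AND frequency > min_frequency (default 0.60, strict) — retained calls
are treated as true strain differences.
"""
from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .models import TruncationReport, VariantRecord

BACTERIAL_TABLE = 11
_TABLE = unambiguous_dna_by_id[BACTERIAL_TABLE]
START_CODONS = tuple(_TABLE.start_codons)
STOP_CODONS = tuple(_TABLE.stop_codons)


def filter_variants(
    records: list[VariantRecord],
    min_coverage: int = 10,
    min_frequency: float = 0.60,
) -> list[VariantRecord]:
    """Keep calls with coverage >= min_coverage and frequency > min_frequency."""
    return [v for v in records if v.coverage >= min_coverage and v.frequency > min_frequency]


def _canonical_key(v: VariantRecord, reference: str | None):
    """Variant identity key; 1-bp homopolymer deletions are left-aligned
    when a reference sequence is available, so the same physical deletion
    called at different positions within a run compares equal."""
    if (
        reference is not None
        and len(v.ref) == 1
        and v.alt == ""
        and 1 <= v.position <= len(reference)
        and reference[v.position - 1] == v.ref
    ):
        pos = v.position
        while pos > 1 and reference[pos - 2] == v.ref:
            pos -= 1
        return (v.contig, pos, v.ref, v.alt)
    return v.key


def unique_to_mutant(
    mutant_table: list[VariantRecord],
    wildtype_table: list[VariantRecord],
    reference: str | None = None,
) -> list[VariantRecord]:
    """Calls present in the mutant but not the wild type, by identity key.

    Comparison is key-based on (contig, position, ref, alt); frequency
    and coverage differences alone never make a call unique. Both tables
    are expected to have been filtered with the same thresholds.
    """
    wt_keys = {_canonical_key(v, reference) for v in wildtype_table}
    seen = set()
    out = []
    for v in mutant_table:
        k = _canonical_key(v, reference)
        if k not in wt_keys and k not in seen:
            seen.add(k)
            out.append(v)
    return out


def _translate_to_stop(cds: str) -> tuple[int, int | None]:
    """(protein length in aa before the first stop, 1-based nt position of
    that stop codon, or None if translation runs off the end)."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return i // 3, i + 1
    return len(cds) // 3, None


def apply_edit(cds: str, position: int, ref: str, alt: str) -> str:
    """Apply a replacement edit (1-based): ``ref`` at ``position`` becomes
    ``alt``; a deletion is an empty ``alt``."""
    if not 1 <= position <= len(cds):
        raise ValueError(f"edit position {position} outside CDS of length {len(cds)}")
    found = cds[position - 1 : position - 1 + len(ref)]
    if found != ref:
        raise ValueError(f"ref allele mismatch at {position}: expected {ref!r}, found {found!r}")
    return cds[: position - 1] + alt + cds[position - 1 + len(ref) :]


def _in_homopolymer_run(cds: str, position: int) -> bool:
    base = cds[position - 1]
    return (position > 1 and cds[position - 2] == base) or (
        position < len(cds) and cds[position] == base
    )


def predict_frameshift(cds: str, edit: tuple[int, str, str]) -> TruncationReport:
    """Predict the protein consequence of an edit to a CDS.

    The CDS must be a complete frame: length divisible by 3, a valid
    start codon (bacterial table 11; alternative starts read as
    formyl-Met) and a terminal stop. The edited sequence is translated
    from codon 1 to the first in-frame stop; the report carries the
    mutant protein length, the percent reduction versus the original,
    and the 1-based nt position of the new stop in the mutant CDS. A
    1-bp deletion inside a homopolymer run of >= 2 identical bases is
    flagged ambiguous: any deleted position in the run yields the same
    sequence. An edit that removes every stop is flagged ``no_stop``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if cds[:3] not in START_CODONS:
        raise ValueError(f"CDS does not begin with a start codon (got {cds[:3]})")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError(f"CDS does not end with a stop codon (got {cds[-3:]})")

    position, ref, alt = edit
    original_aa = len(cds) // 3 - 1
    if ref == alt:  # identity edit
        mutant = cds
        ambiguous = False
    else:
        mutant = apply_edit(cds, position, ref, alt)
        ambiguous = len(ref) == 1 and alt == "" and _in_homopolymer_run(cds, position)

    mutant_aa, stop_nt = _translate_to_stop(mutant)
    return TruncationReport(
        original_length_aa=original_aa,
        mutant_length_aa=mutant_aa,
        percent_reduction=percent_reduction(original_aa, mutant_aa),
        stop_position_nt=stop_nt,
        homopolymer_ambiguous=ambiguous,
        no_stop=stop_nt is None,
    )


def translate_cds(cds: str) -> str:
    """Translate a complete CDS (table 11), alternative starts as Met,
    stopping at the first stop codon."""
    aa = str(Seq(cds).translate(table=BACTERIAL_TABLE, to_stop=True))
    if aa and cds[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


def orf_protein_length(orf_length_nt: int) -> int:
    """Protein length encoded by an ORF of ``orf_length_nt`` nucleotides:
    nt/3 - 1 (the stop codon is not translated)."""
    if orf_length_nt < 6 or orf_length_nt % 3 != 0:
        raise ValueError("ORF length must be a multiple of 3 and >= 6")
    return orf_length_nt // 3 - 1


def percent_reduction(original_aa: int, mutant_aa: int) -> float:
    """Size reduction of the mutant protein vs the original, in percent."""
    if original_aa <= 0:
        raise ValueError("original length must be positive")
    return (1.0 - mutant_aa / original_aa) * 100.0
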