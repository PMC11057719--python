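"""Reporter-construct geometry for the DR-*white* double-strand-break assay.

The assay's broken repeat (``Sce.white``) differs from the restored wild-type
*white* amplicon by a 23-bp insertion that carries the 18-bp I-SceI
recognition sequence plus duplicated SacI-site nucleotides.  Gene conversion
from the downstream donor removes the insertion and restores an intact SacI
site (GAGCTC), so homologous recombination appears in a trace decomposition
as a net deletion equal to the insertion length (-23 for the canonical
construct).

Coordinates are 1-based, closed, top strand (the strand read by the
sequencing primer).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ISCEI_RECOGNITION = "TAGGGATAACAGGGTAAT"
SACI_MOTIF = "GAGCTC"
DNA_ALPHABET = "ACGT"


class ConstructError(ValueError):
    """The construct violates the DR-*white* geometry invariants."""


class AmbiguousSiteError(ConstructError):
    """The recognition sequence is absent or occurs more than once."""


def _count_occurrences(haystack: str, needle: str) -> int:
    """Count possibly-overlapping occurrences of ``needle``."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


@dataclass(frozen=True)
class ReferenceConstruct:
    """Wild-type and Sce.*white* amplicons plus break-site geometry.

    Parameters
    ----------
    wildtype_seq
        The restored *white* amplicon, carrying an intact SacI site.
    sce_seq
        The same amplicon with the break-site insertion.
    recognition_start
        1-based start of the I-SceI recognition sequence within ``sce_seq``.
    insertion_len
        Length of the insertion in bp (23 for the canonical construct).
    cut_offset
        Offset in bp from ``recognition_start`` to the modeled break point.
    """

    wildtype_seq: str
    sce_seq: str
    recognition_start: int
    insertion_len: int = 23
    cut_offset: int = 9
    sacI_motif: str = SACI_MOTIF
    recognition_seq: str = ISCEI_RECOGNITION

    def __post_init__(self) -> None:
        wt, sce = self.wildtype_seq, self.sce_seq
        if not set(wt) <= set(DNA_ALPHABET) or not set(sce) <= set(DNA_ALPHABET):
            raise ConstructError("sequences must be uppercase A/C/G/T")
        if len(sce) - len(wt) != self.insertion_len:
            raise ConstructError(
                f"length(sce_seq) - length(wildtype_seq) = {len(sce) - len(wt)}, "
                f"expected insertion_len = {self.insertion_len}"
            )
        locus = self.insertion_locus
        if sce[: locus - 1] + sce[locus - 1 + self.insertion_len :] != wt:
            raise ConstructError(
                "removing insertion_len bases at the insertion locus of sce_seq "
                "does not restore wildtype_seq"
            )
        if self.insertion_len > 0:
            lo = max(0, locus - 1 - len(self.sacI_motif))
            if wt.find(self.sacI_motif, lo, locus - 1 + len(self.sacI_motif)) < 0:
                raise ConstructError(
                    f"wildtype_seq lacks {self.sacI_motif} at the insertion locus"
                )
            rs = self.recognition_start
            if sce[rs - 1 : rs - 1 + len(self.recognition_seq)] != self.recognition_seq:
                raise ConstructError(
                    f"sce_seq does not carry the recognition sequence at "
                    f"position {rs}"
                )

    @property
    def insertion_locus(self) -> int:
        """1-based position in ``sce_seq`` of the first inserted base.

        Found as the first position where the two amplicons disagree; for a
        degenerate construct with ``insertion_len == 0`` this is
        ``len(sce_seq) + 1``.
        """
        wt, sce = self.wildtype_seq, self.sce_seq
        for i, (a, b) in enumerate(zip(wt, sce)):
            if a != b:
                return i + 1
        return len(wt) + 1


def build_sce_from_wildtype(wildtype_seq: str) -> tuple[str, int]:
    """Insert the canonical 23-bp I-SceI cassette at the SacI site.

    The wild-type amplicon must carry GAGCTC exactly once.  The cassette
    duplicates the first five SacI nucleotides (GAGCT) ahead of the 18-bp
    recognition sequence, so removing the 23 inserted bases restores the
    wild type exactly and the SacI-derived nucleotides persist at the
    insertion site.

    Returns ``(sce_seq, recognition_start)`` with 1-based coordinates.
    """
    if _count_occurrences(wildtype_seq, SACI_MOTIF) != 1:
        raise AmbiguousSiteError(
            f"wildtype amplicon must contain {SACI_MOTIF} exactly once"
        )
    i = wildtype_seq.find(SACI_MOTIF)
    sce = wildtype_seq[: i + 5] + ISCEI_RECOGNITION + wildtype_seq[i:]
    return sce, i + 5 + 1


def locate_recognition_site(ref: ReferenceConstruct) -> int:
    """Return the 1-based break position in ``sce_seq``.

    The I-SceI recognition sequence must occur exactly once; the break is
    modeled ``cut_offset`` bases into the site, i.e. at
    ``recognition_start + cut_offset`` (the last intact position before the
    cut).
    """
    n = _count_occurrences(ref.sce_seq, ref.recognition_seq)
    if n != 1:
        raise AmbiguousSiteError(
            f"recognition sequence occurs {n} times in sce_seq (need exactly 1)"
        )
    return ref.recognition_start + ref.cut_offset


def expected_hr_shift(ref: ReferenceConstruct) -> int:
    """Net indel size diagnostic of HR gene conversion (deletions negative).

    Conversion from the donor removes the whole insertion, so the HR
    signature is ``-insertion_len`` (-23 for the canonical construct).
    """
    return -ref.insertion_len


def write_reference_fasta(ref: ReferenceConstruct, path: str | Path) -> None:
    """Write the two amplicons as FASTA records ``wildtype`` and ``sce_white``."""
    records = [
        SeqRecord(Seq(ref.wildtype_seq), id="wildtype", description=""),
        SeqRecord(Seq(ref.sce_seq), id="sce_white", description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(
    fasta_path: str | Path,
    config_path: str | Path | None = None,
    *,
    recognition_start: int | None = None,
    insertion_len: int = 23,
    cut_offset: int = 9,
) -> ReferenceConstruct:
    """Load a construct from FASTA plus break-site metadata.

    The FASTA must contain records named ``wildtype`` and ``sce_white``.
    Metadata comes either from a TOML file with keys ``recognition_start``,
    ``insertion_len`` and ``cut_offset``, or from the keyword arguments.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    missing = {"wildtype", "sce_white"} - set(records)
    if missing:
        raise ConstructError(f"FASTA is missing records: {sorted(missing)}")
    if config_path is not None:
        with open(config_path, "rb") as fh:
            cfg = tomllib.load(fh)
        recognition_start = int(cfg["recognition_start"])
        insertion_len = int(cfg.get("insertion_len", insertion_len))
        cut_offset = int(cfg.get("cut_offset", cut_offset))
    if recognition_start is None:
        raise ConstructError("recognition_start must be given (config or keyword)")
    return ReferenceConstruct(
        wildtype_seq=records["wildtype"],
        sce_seq=records["sce_white"],
        recognition_start=recognition_start,
        insertion_len=insertion_len,
        cut_offset=cut_offset,
    )
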