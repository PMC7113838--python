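"""Deterministic splice-consequence arithmetic for donor-site variants.

Models the two aberrant products of a canonical +1 splice-donor substitution:
whole-exon skipping (frame decided by the exon length modulo 3, with the
deleted residue interval read off the translated products) and activation of
a cryptic donor inside the downstream intron (partial intron retention,
scanned for a premature termination codon, PTC). Protein-level deletions are
named HGVS-style with three-letter residue codes.

The packaged prostacyclin-synthase-like transcript model is synthetic: a
constructed five-exon minigene whose internal exon 4 is 144 nt and
codon-aligned (codons 127-174) and whose intron 4 carries an early in-frame
stop within the first retained codons, so every printed consequence of the
donor variant is checkable without any external sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "TranscriptModel",
    "SpliceOutcome",
    "exon_skip",
    "cryptic_donor",
    "protein_interval_name",
    "ptgis_transcript_fixture",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/intron model of one protein-coding transcript.

    ``exons`` are ordered exonic sequences (5'->3'); ``cds_offset`` is the
    0-based offset of the start codon within the spliced transcript (the
    5' UTR length, contained in exon 1); ``introns`` maps the 1-based intron
    index (intron i follows exon i) to its sequence.
    """

    exons: tuple[str, ...]
    cds_offset: int
    cds_length: int
    introns: Mapping[int, str] = field(default_factory=dict)
    name: str = "transcript"

    def __post_init__(self) -> None:
        if any(len(e) == 0 for e in self.exons):
            raise ValueError("exon lengths must be positive")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if self.cds_offset + self.cds_length > sum(len(e) for e in self.exons):
            raise ValueError("CDS extends past the spliced transcript")

    @property
    def spliced(self) -> str:
        return "".join(self.exons)

    @property
    def cds(self) -> str:
        return self.spliced[self.cds_offset : self.cds_offset + self.cds_length]

    @property
    def protein(self) -> str:
        """Reference protein, stop codon excluded."""
        return str(Seq(self.cds).translate()).rstrip("*")

    def exon_cds_span(self, exon_index: int) -> tuple[int, int]:
        """0-based [start, end) of an exon within CDS coordinates."""
        start = sum(len(e) for e in self.exons[: exon_index - 1]) - self.cds_offset
        return start, start + len(self.exons[exon_index - 1])


@dataclass(frozen=True)
class SpliceOutcome:
    event: str  # exon_skip / cryptic_donor
    frame_preserving: bool
    deleted_nt: int
    deleted_residues: tuple[int, int] | None  # inclusive 1-based interval
    introduces_ptc: bool
    ptc_codon_index: int | None = None

    def __post_init__(self) -> None:
        if self.event == "exon_skip" and self.frame_preserving != (self.deleted_nt % 3 == 0):
            raise ValueError("frame flag inconsistent with deleted length")

    @property
    def n_deleted_residues(self) -> int | None:
        if self.deleted_residues is None:
            return None
        return self.deleted_residues[1] - self.deleted_residues[0] + 1


def _translate_to_stop(seq: str) -> tuple[str, int | None]:
    """Translate codon-by-codon; returns (peptide, 0-based stop codon index)."""
    peptide = []
    for k in range(0, len(seq) - 2, 3):
        codon = seq[k : k + 3]
        if codon in _STOPS:
            return "".join(peptide), k // 3
        peptide.append(str(Seq(codon).translate()))
    return "".join(peptide), None


def exon_skip(model: TranscriptModel, exon_index: int) -> SpliceOutcome:
    """Consequence of skipping one internal, fully coding exon.

    The deleted nucleotide count is the exon length; the reading frame is
    preserved iff it is a multiple of 3, in which case the deleted residue
    interval is located by comparing the translated products (for a
    codon-aligned exon this is exactly the exon's codon interval).
    """
    n_exons = len(model.exons)
    if exon_index <= 1 or exon_index >= n_exons:
        raise ValueError(
            f"exon {exon_index} is not internal (transcript has {n_exons} exons); "
            "first/last-exon skipping is unsupported"
        )
    s, e = model.exon_cds_span(exon_index)
    if s < 0 or e > model.cds_length:
        raise ValueError(f"exon {exon_index} is not fully coding")
    deleted_nt = len(model.exons[exon_index - 1])
    frame_preserving = deleted_nt % 3 == 0

    skipped = "".join(x for i, x in enumerate(model.exons, start=1) if i != exon_index)
    new_pep, _stop = _translate_to_stop(skipped[model.cds_offset :])
    ref = model.protein

    if not frame_preserving:
        return SpliceOutcome(
            "exon_skip", False, deleted_nt, None,
            introduces_ptc=len(new_pep) < len(ref),
            ptc_codon_index=(len(new_pep) + 1) if len(new_pep) < len(ref) else None,
        )

    expected = len(ref) - deleted_nt // 3
    if len(new_pep) < expected:
        # frame-preserving but an out-of-exon-phase junction created a stop
        return SpliceOutcome(
            "exon_skip", True, deleted_nt, None, True, len(new_pep) + 1
        )
    prefix = 0
    while prefix < len(new_pep) and new_pep[prefix] == ref[prefix]:
        prefix += 1
    start = prefix + 1
    end = prefix + deleted_nt // 3
    return SpliceOutcome("exon_skip", True, deleted_nt, (start, end), False, None)


def cryptic_donor(model: TranscriptModel, intron_index: int, offset_nt: int) -> SpliceOutcome:
    """Consequence of a cryptic donor ``offset_nt`` bases into an intron.

    The first ``offset_nt`` intronic bases are retained after the upstream
    exon; the resulting reading frame is scanned for the first stop codon.
    ``introduces_ptc`` is true when that stop precedes the natural stop
    codon's position in the retained-intron transcript.
    """
    if intron_index not in model.introns:
        raise ValueError(f"intron {intron_index} sequence missing from the model")
    intron = model.introns[intron_index]
    if offset_nt > len(intron) or offset_nt < 0:
        raise ValueError(f"offset {offset_nt} exceeds intron length {len(intron)}")
    retained = intron[:offset_nt]
    new_spliced = (
        "".join(model.exons[:intron_index])
        + retained
        + "".join(model.exons[intron_index:])
    )
    new_cds_region = new_spliced[model.cds_offset :]
    _pep, stop_idx = _translate_to_stop(new_cds_region)
    natural_stop_nt = model.cds_length - 3 + offset_nt  # position after the insertion
    if stop_idx is None or stop_idx * 3 >= natural_stop_nt:
        return SpliceOutcome("cryptic_donor", offset_nt % 3 == 0, offset_nt, None, False, None)
    return SpliceOutcome(
        "cryptic_donor", offset_nt % 3 == 0, offset_nt, None, True, stop_idx + 1
    )


def protein_interval_name(outcome: SpliceOutcome, protein: str) -> str:
    """HGVS-style deletion label, e.g. ``p.Thr127_Arg174del``.

    Only defined for frame-preserving outcomes carrying a residue interval;
    a single-residue deletion uses the one-position form.
    """
    if not outcome.frame_preserving or outcome.deleted_residues is None:
        raise ValueError("protein deletion naming requires a frame-preserving interval")
    start, end = outcome.deleted_residues
    if not 1 <= start <= end <= len(protein):
        raise ValueError(f"interval {start}-{end} outside protein of length {len(protein)}")
    aa_start = seq3(protein[start - 1])
    if start == end:
        return f"p.{aa_start}{start}del"
    aa_end = seq3(protein[end - 1])
    return f"p.{aa_start}{start}_{aa_end}{end}del"


# ---------------------------------------------------------------------------
# packaged synthetic transcript fixture

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

#: CDS spans of the five exons in the fixture (0-based, nt): exon 4 is the
#: 144-nt, codon-aligned internal exon covering codons 127-174.
_FIXTURE_CDS_BREAKS = (0, 186, 306, 378, 522, 1503)
_UTR5 = "GGCAGCGGCAGC"
_UTR3 = "AGCTGCCTGAGCCCTGAGGCAGCAGCCTGA"


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def ptgis_transcript_fixture() -> TranscriptModel:
    """Synthetic prostacyclin-synthase-like five-exon transcript model.

    Constructed (not downloaded) so that the printed consequences of a +1
    donor substitution after exon 4 hold exactly: exon 4 is 144 nt and
    codon-aligned, spanning Thr127..Arg174 of the 500-residue protein, and
    intron 4 places a stop codon within the first two retained codons so a
    cryptic donor 371 nt downstream yields a PTC immediately after the
    exon-4-derived product.
    """
    rng = np.random.default_rng(20)
    codons = [str(c) for c in rng.choice(_SENSE_CODONS, size=500)]
    codons[0] = "ATG"
    codons[125] = "GGT"  # Gly126: flank distinct from the deleted run
    codons[126] = "ACT"  # Thr127
    codons[173] = "CGT"  # Arg174
    codons[174] = "CTG"  # Leu175: flank distinct from the deleted run
    cds = "".join(codons) + "TAA"

    b = _FIXTURE_CDS_BREAKS
    exons = (
        _UTR5 + cds[b[0] : b[1]],
        cds[b[1] : b[2]],
        cds[b[2] : b[3]],
        cds[b[3] : b[4]],
        cds[b[4] :] + _UTR3,
    )
    introns = {
        i: "GT" + _filler(rng, 116) + "AG" for i in (1, 2, 3)
    }
    # intron 4: donor GT, then an in-frame TAA one codon into the retention
    introns[4] = "GT" + "A" + "TAA" + _filler(rng, 892) + "AG"
    return TranscriptModel(
        exons=exons,
        cds_offset=len(_UTR5),
        cds_length=len(cds),
        introns=introns,
        name="PTGIS-like synthetic minigene",
    )
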