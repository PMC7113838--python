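"""Splice-consequence arithmetic for a +1 donor-site variant.

A canonical GT->AT donor substitution after exon 4 yields two aberrant
transcripts: complete exon-4 skipping and a cryptic donor 371 nt into the
intron. This walks both on the packaged synthetic transcript model.
"""

from pahrare.consequence import (
    cryptic_donor,
    exon_skip,
    protein_interval_name,
    ptgis_transcript_fixture,
)

model = ptgis_transcript_fixture()
print(f"transcript: {model.name}")
print(f"exon lengths: {[len(e) for e in model.exons]} nt, protein {len(model.protein)} aa")

skip = exon_skip(model, 4)
print(f"\nexon-4 skip: {skip.deleted_nt} nt removed, "
      f"frame-preserving = {skip.frame_preserving}")
print(f"  deletes {skip.n_deleted_residues} residues -> "
      f"{protein_interval_name(skip, model.protein)}")

cd = cryptic_donor(model, 4, 371)
print(f"\ncryptic donor +371 nt: retains {cd.deleted_nt} intronic bases")
print(f"  premature termination codon: {cd.introduces_ptc} "
      f"(codon {cd.ptc_codon_index}; exon-4 product ends at codon 174)")

# 144 nt is a multiple of 3, so the skip is in-frame and excises exactly 48
# residues (Thr127..Arg174); the cryptic donor shifts into intronic sequence
# and truncates the protein immediately after the exon-4-derived product.
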