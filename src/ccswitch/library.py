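"""Built-in peptide set for the phospho-switchable coiled-coil heterodimer.

SYNTHETIC RECONSTRUCTIONS.  The sequences below are rebuilt from the
published design rules for the acidic/basic four-heptad heterodimer family
(E at e/g on the acidic strand, K at e/g on the basic strand, an Asn-Asn'
pair at a4 to fix register and orientation, a basophilic-kinase RRXS motif
with Ser at a2 and Arg-Arg at e1/f1, and an Ile->Ser a2' substitution on
the acidic partner), not copied from any printed table.  They reproduce the
designed register chemistry exactly; side-chain identities outside the
stated rules follow the canonical Ile@a / Ala@b,c / Leu@d / Gln@f pattern
of this peptide family.  Gly/Trp caps (register '-') are included for the
synthesis-style termini and 280-nm concentration determination.

The fusion constructs are likewise synthetic stand-ins: the fluorescent
protein cores are generic beta-barrel-sized placeholders, *not* the real
mCitrine/mVenus/mApple sequences, so their masses are illustrative only.
"""

from __future__ import annotations

from dataclasses import replace

from .peptides import RegisteredPeptide, insert_kinase_motif, substitute_at_register

_CAPS = dict(n_flank="G", c_flank="GW", n_term_mod="acetyl", c_term_mod="amide")

#: acidic parent: Ile at every a, Asn at a4; E at e and g, Q at f.
CC_DI_A_N4 = RegisteredPeptide(
    name="CC-Di-A_N4",
    sequence="G" + "IAALEQE" * 3 + "NAALEQE" + "GW",
    register_offset=0,
    **_CAPS,
)

#: basic parent: as above with K at e and g.
CC_DI_B_N4 = RegisteredPeptide(
    name="CC-Di-B_N4",
    sequence="G" + "IAALKQK" * 3 + "NAALKQK" + "GW",
    register_offset=0,
    **_CAPS,
)

#: acidic partner with Ile->Ser at a2 (Ser-Ser' pairing against the switch).
CC_DI_A_S = replace(
    substitute_at_register(CC_DI_A_N4, "a", 2, "S"), name="CC-Di-A_S"
)

#: switch peptide: RRxS grafted so Ser sits at a2, Arg-Arg at e1/f1.
CC_DI_B_RRS = replace(
    insert_kinase_motif(CC_DI_B_N4, "RRxS", "a", 2), name="CC-Di-B_RRS"
)

#: phosphorylated switch peptide (phosphoserine at a2).
CC_DI_B_RRPS = replace(
    CC_DI_B_RRS,
    name="CC-Di-B_RRpS",
    sidechain_mods=((CC_DI_B_RRS.index_of("a", 2), "phospho"),),
)

#: hybrid Snf7-style amphipathic membrane-targeting 13-mer (synthetic
#: stand-in): Trp-bearing hydrophobic face on one side of the wheel,
#: charged/polar residues on the other.
HYB_SNF7_1_13 = RegisteredPeptide(
    name="hybSnf7(1-13)", sequence="MWSKLFSLWKNLA", register_offset=0
)

PEPTIDES = {
    p.name: p
    for p in (
        CC_DI_A_N4,
        CC_DI_B_N4,
        CC_DI_A_S,
        CC_DI_B_RRS,
        CC_DI_B_RRPS,
        HYB_SNF7_1_13,
    )
}

_LINKER = "GSGSGS"
_FP_STANDIN = (  # generic 11-strand beta-barrel-sized placeholder, ~27 kDa
    "MVSKGEELFTGVVPILVELDGDVNGHKFSVSGEGEGDATYGKLTLKFICTTGKLPVPWPT"
    "LVTTLGYGLQCFARYPDHMKQHDFFKSAMPEGYVQERTIFFKDDGNYKTRAEVKFEGDTL"
    "VNRIELKGIDFKEDGNILGHKLEYNYNSHNVYITADKQKNGIKANFKIRHNIEDGSVQLA"
    "DHYQQNTPIGDGPVLLPDNHYLSYQSALSKDPNEKRDHMVLLEFVTAAGITLGMDELYK"
)

#: membrane-tether anchor: CC module, fluorescent protein, decahistidine tag.
FUSION_ANCHOR = (
    "anchor CC-Di-A_S-FP-H10 (synthetic stand-in)",
    CC_DI_A_S.core + _LINKER + _FP_STANDIN + _LINKER + "H" * 10,
)

#: avidity switch A: MTS, fluorescent protein, H6, acidic CC module.
FUSION_SWITCH_A = (
    "SwitchA hybSnf7-FP-H6-CC-Di-A_S (synthetic stand-in)",
    HYB_SNF7_1_13.sequence + _LINKER + _FP_STANDIN + "H" * 6 + _LINKER + CC_DI_A_S.core,
)

#: avidity switch B: MTS, fluorescent protein, H6, basic switch CC module.
FUSION_SWITCH_B = (
    "SwitchB hybSnf7-FP-H6-CC-Di-B_RRS (synthetic stand-in)",
    HYB_SNF7_1_13.sequence + _LINKER + _FP_STANDIN + "H" * 6 + _LINKER + CC_DI_B_RRS.core,
)

FUSIONS = dict([FUSION_ANCHOR, FUSION_SWITCH_A, FUSION_SWITCH_B])
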