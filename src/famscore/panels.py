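"""Built-in marker panels.

The four-SNP autism panel combines variants in PITX1, ATP2B2, SLC25A12 and
EN2 that have each shown association with autism in candidate-gene studies.
ATP2B2 follows a recessive transmission model (risk homozygotes score 2, all
other genotypes 0); the other three are coded additively. Risk-allele
frequencies are parental estimates from two multiplex-family collections: an
AGRE-style sample (all affected children and parents genotyped, unaffected
siblings not genotyped) and a Seattle-style sample (unaffected siblings
genotyped and used as true controls).
"""

from .datatypes import SnpDef

_PANEL_FREQS = {
    "agre": (0.89, 0.45, 0.90, 0.75),
    "seattle": (0.90, 0.41, 0.90, 0.72),
}


def autism_four_snp_panel(sample: str = "agre") -> list[SnpDef]:
    """The PITX1 / ATP2B2 / SLC25A12 / EN2 risk-score panel.

    Parameters
    ----------
    sample
        ``"agre"`` or ``"seattle"``: which collection's parental risk-allele
        frequency estimates to attach.
    """
    try:
        f_pitx1, f_atp2b2, f_slc25a12, f_en2 = _PANEL_FREQS[sample]
    except KeyError:
        raise ValueError(f"unknown sample {sample!r}; use 'agre' or 'seattle'")
    return [
        SnpDef("rs6872664", "5", "C", "T", risk_allele="C", mode="additive",
               risk_freq=f_pitx1),
        SnpDef("rs35678", "3", "T", "C", risk_allele="T", mode="recessive",
               risk_freq=f_atp2b2),
        SnpDef("rs2292813", "2", "C", "T", risk_allele="C", mode="additive",
               risk_freq=f_slc25a12),
        SnpDef("rs1861972", "7", "A", "G", risk_allele="A", mode="additive",
               risk_freq=f_en2),
    ]


#: gene symbol per panel marker, for report tables
PANEL_GENES = {
    "rs6872664": "PITX1",
    "rs35678": "ATP2B2",
    "rs2292813": "SLC25A12",
    "rs1861972": "EN2",
}
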