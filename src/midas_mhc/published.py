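"""Published inputs of the Midas cichlid MHC IIB survey.

Two pieces of the original survey are reproduced here because downstream
steps consume them as inputs rather than compute them:

* the sampling design -- 14 populations in six Nicaraguan lakes (two large
  tectonic lakes, four crater lakes), each population tied to one habitat
  class, with the number of genotyped individuals per population; and
* the site-level positive-selection scans -- per-method lists of positively
  selected codon positions (1-based within the 47-codon exon-2 fragment)
  reported by CodeML (M2a/M8 Bayes empirical Bayes), MEME (shared with the
  unconstrained BUSTED fit) and the MrBayes Ny98 model.  Fitting those codon
  models is outside this package; their site lists feed the >=2-method
  consensus in :mod:`midas_mhc.selection`.
"""

from __future__ import annotations

import pandas as pd

from .selection import MethodPSSReport

__all__ = ["study_design", "published_pss_reports", "SITE41_EXCLUSION"]

# (population, lake, lake_type, habitat, n individuals)
_DESIGN = [
    ("Nicaragua_citrinellus", "Nicaragua", "tectonic", "shallow_benthic", 24),
    ("Nicaragua_labiatus", "Nicaragua", "tectonic", "rocky", 25),
    ("Managua_citrinellus", "Managua", "tectonic", "shallow_benthic", 20),
    ("Managua_labiatus", "Managua", "tectonic", "rocky", 4),
    ("Masaya_cf_citrinellus", "Masaya", "crater", "shallow_benthic", 27),
    ("Masaya_cf_labiatus", "Masaya", "crater", "rocky", 18),
    ("AsososcaLeon_benthic", "AsososcaLeon", "crater", "shallow_benthic", 23),
    ("AsososcaLeon_limnetic", "AsososcaLeon", "crater", "limnetic", 20),
    ("Apoyo_astorquii", "Apoyo", "crater", "shallow_benthic", 20),
    ("Apoyo_chancho", "Apoyo", "crater", "deep_benthic", 21),
    ("Apoyo_zaliosus", "Apoyo", "crater", "limnetic", 21),
    ("Xiloa_amarillo", "Xiloa", "crater", "shallow_benthic", 22),
    ("Xiloa_xiloaensis", "Xiloa", "crater", "deep_benthic", 11),
    ("Xiloa_sagittae", "Xiloa", "crater", "limnetic", 31),
]


def study_design() -> pd.DataFrame:
    """The 14-population sampling design with per-population sample sizes.

    Returns one row per population (columns: population, lake, lake_type,
    habitat, n).  287 individuals in total.
    """
    return pd.DataFrame(
        _DESIGN, columns=["population", "lake", "lake_type", "habitat", "n"]
    )


# Codon positions under positive selection per method (1-based, 1..47).
_CODEML_SITES = [1, 3, 10, 12, 13, 22, 28, 35, 40, 42, 44, 45, 46]
_MEME_SITES = [1, 3, 5, 12, 13, 16, 21, 22, 35, 36, 39, 42, 44, 45, 46, 47]
_MRBAYES_SITES = [1, 3, 13, 22, 28, 35, 36, 42, 45, 46]

#: codon 41 carries the 3-bp deletion in one allele and was excluded from the
#: codon-model fits; pass this to :func:`midas_mhc.selection.consensus_pss`.
SITE41_EXCLUSION = (41,)


def published_pss_reports() -> list[MethodPSSReport]:
    """Per-method positively-selected-site reports for the exon-2 fragment."""
    return [
        MethodPSSReport(method="CodeML", sites=list(_CODEML_SITES)),
        MethodPSSReport(method="MEME", sites=list(_MEME_SITES)),
        MethodPSSReport(method="MrBayes", sites=list(_MRBAYES_SITES)),
    ]
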