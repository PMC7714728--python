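"""Frozen cofolding reference energies for cross-engine ranking checks.

Twenty designed Watson-Crick duplexes (both strands 5'->3', fully
complementary) with their cofold minimum free energies, computed once with
RNAcofold (ViennaRNA 2.7.2, Turner 2004 parameters, 37 degC) and frozen
here.  The internal stacking engine omits duplex-initiation and terminal
terms, so its absolute values differ from these MFEs by a roughly constant
offset; what is expected to agree is the *ranking* of duplex stabilities.
"""

from __future__ import annotations

__all__ = ["REFERENCE_DUPLEXES"]

# (top strand 5'->3', bottom strand 5'->3', RNAcofold MFE in kcal/mol)
REFERENCE_DUPLEXES: list[tuple[str, str, float]] = [
    ("GAACCU", "AGGUUC", -6.30),
    ("UUAAUAAAUCC", "GGAUUUAUUAA", -9.60),
    ("CGUGUA", "UACACG", -5.60),
    ("GGAACAUG", "CAUGUUCC", -10.00),
    ("GGCCAAUCUCG", "CGAGAUUGGCC", -19.30),
    ("UACCUUCCACA", "UGUGGAAGGUA", -16.80),
    ("UCUCC", "GGAGA", -5.60),
    ("GCCUCCCCCUAU", "AUAGGGGGAGGC", -24.30),
    ("ACAGAA", "UUCUGU", -4.70),
    ("UGUCAUACCGAA", "UUCGGUAUGACA", -17.40),
    ("AAGGC", "GCCUU", -5.10),
    ("CUCGCGGUCA", "UGACCGCGAG", -18.10),
    ("GAUGCGGC", "GCCGCAUC", -14.00),
    ("CUUGACCGG", "CCGGUCAAG", -14.60),
    ("GAAAAU", "AUUUUC", -1.60),
    ("GAACA", "UGUUC", -3.00),
    ("AUCAAGCC", "GGCUUGAU", -10.70),
    ("GGAUUGCCCU", "AGGGCAAUCC", -17.30),
    ("ACACCAGGC", "GCCUGGUGU", -16.10),
    ("CCCAA", "UUGGG", -5.10),
]
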