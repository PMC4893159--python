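"""Robust-Z hit calling and S/TQ motif counting on a small PTM table.

SILAC ratio distributions are heavy-tailed, so screens are standardized
with a median/MAD Z rather than mean/SD; the ATM/ATR consensus motif
(S or T followed by Q) is counted among phospho-sites.
"""

import pandas as pd

import uvddr
from uvddr.screen_io import PTMSiteTable

# A toy screen: one strong responder (UVSSA-like) on a quiet background.
ratios = {"CSB": 0.1, "UVSSA": 3.2, "XPA": -0.2, "GTF2H1": 0.3,
          "ACTB": 0.0, "GAPDH": -0.1, "MYC": -0.4}
z = uvddr.robust_z(ratios)
calls = uvddr.call_hits(z, threshold=2.0, policy=uvddr.ScreenDirectionPolicy(),
                        screen_id="csb_interactome")
print(calls.to_string(index=False))
# UVSSA's ratio is >2 robust SDs above the screen median -> the only hit.

sites = PTMSiteTable("phospho", pd.DataFrame({
    "protein_id": ["H2AFX", "BRCA1", "CHEK1", "MYC"],
    "residue":    ["S",     "S",     "T",     "S"],
    "position":   [140,     988,     68,      62],
    "window":     ["AAASQEA", "LRVSQKA", "GLETQRA", "LPTSPLA"],
    "log2_ratio": [2.5,     1.8,     2.1,     0.0],
}))
z_sites = uvddr.robust_z(sites.data["log2_ratio"])
n_total, n_up = uvddr.count_stq(sites, increased={("H2AFX", 140), ("CHEK1", 68)})
print(f"\nS/TQ sites: {n_total} of {len(sites.data)}; UV-increased S/TQ: {n_up}")
# 3 of the 4 windows carry the S/T-Q consensus; 2 of those are UV-induced.

protein_level = uvddr.rollup_sites(sites, z_sites)
print("\nsite -> protein rollup (max |z| site kept):")
print(protein_level.to_string(index=False))
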