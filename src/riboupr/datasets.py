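"""Published summary tables used as inputs.

These are the *printed* summary numbers of the yeast ER-stress/longevity
screen (per-strain mean replicative lifespan, cohort sizes, percent change
and rank-sum p-values, plus the RT-PCR HAC1 spliced fractions). The raw
per-cell and sequencing data behind them were never deposited; the printed
summaries serve as inputs for re-deriving the screen arithmetic and as
scenario parameters for the synthetic generators.

p-values printed as "<0.0001" are stored as the upper bound 0.0001; only
comparisons against alpha = 0.05 are ever made with them.
"""

from __future__ import annotations

import pandas as pd

# strain, category, mutant mean RLS, mutant N, control mean RLS, control N,
# printed % mean RLS change, printed p-value string, numeric p bound,
# downstream UPR target (False for the two upstream sensor genes)
_RLS_SCREEN_ROWS = [
    ("ire1Δ", "UPR sensor", 26.1, 315, 26.4, 315, -1.1, "0.9562", 0.9562, False),
    ("hac1Δ", "UPR sensor", 26.8, 220, 26.8, 220, 0.0, "0.7649", 0.7649, False),
    ("ero1-DAmP", "oxidoreductase", 28.1, 160, 22.0, 160, 28.1, "<0.0001", 0.0001, True),
    ("eug1Δ", "oxidoreductase", 29.8, 205, 26.8, 225, 11.2, "0.0037", 0.0037, True),
    ("mpd1Δ", "oxidoreductase", 27.6, 115, 23.6, 115, 16.9, "0.0206", 0.0206, True),
    ("pdi1-DAmP", "oxidoreductase", 24.7, 70, 25.2, 70, -2.0, "0.6599", 0.6599, True),
    ("hrd1Δ", "ERAD", 29.4, 325, 24.9, 364, 18.1, "<0.0001", 0.0001, True),
    ("der1Δ", "ERAD", 29.0, 295, 24.9, 314, 16.5, "<0.0001", 0.0001, True),
    ("sel1Δ", "ERAD", 20.0, 119, 26.3, 120, -24.0, "<0.0001", 0.0001, True),
    ("alg12Δ", "N-glycosylation", 30.7, 345, 26.4, 404, 16.3, "<0.0001", 0.0001, True),
    ("alg3Δ", "N-glycosylation", 28.5, 240, 26.0, 240, 9.6, "0.0027", 0.0027, True),
    ("die2Δ", "N-glycosylation", 21.3, 80, 25.6, 80, -16.8, "0.0032", 0.0032, True),
    ("ost3Δ", "N-glycosylation", 28.4, 75, 23.7, 75, 19.8, "0.0058", 0.0058, True),
    ("ost6Δ", "N-glycosylation", 25.3, 80, 24.6, 80, 2.8, "0.4617", 0.4617, True),
    ("bst1Δ", "protein trafficking", 33.8, 235, 27.0, 245, 25.2, "<0.0001", 0.0001, True),
    ("kar2-DAmP", "chaperone", 15.5, 70, 25.2, 70, -38.5, "<0.0001", 0.0001, True),
]

_COLUMNS = [
    "strain",
    "category",
    "mutant_mean",
    "mutant_n",
    "control_mean",
    "control_n",
    "printed_pct_change",
    "p_printed",
    "p_value",
    "downstream_target",
]


def rls_screen_summary() -> pd.DataFrame:
    """Printed per-strain summary of the ER-stress-gene lifespan screen."""
    return pd.DataFrame(_RLS_SCREEN_ROWS, columns=_COLUMNS)


# RT-PCR densitometry: percent of HAC1 mRNA in the spliced form per condition.
HAC1_SPLICED_PERCENT = {
    "WT": 1.0,
    "WT_TM": 31.0,  # wild type + 1 ug/ml tunicamycin
    "alg12": 7.0,
    "bst1": 21.0,
}

# Fold increases in Hac1p production seen by ribosome profiling; used as
# footprint fold-change scenario parameters for the HAC1-like synthetic gene.
HAC1_FOOTPRINT_FOLD = {
    "WT_TM": 8.0,  # strong induction under acute tunicamycin stress
    "alg12": 3.0,
    "bst1": 12.0,
}
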