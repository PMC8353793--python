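"""Nuclear-export classification from paired whole-cell / cytoplasmic DE results.

A transcript whose cytoplasmic abundance changes more than ``cyt_threshold``
fold between conditions while its whole-cell (steady-state) abundance stays
within ``wct_threshold`` fold is inferred to have altered nuclear export:
stimulated when the cytoplasmic change is up, inhibited when down. The rule
operates on fold changes only; an optional p-value condition on the
cytoplasmic side can be switched on. Features present in only one
compartment's (post-filter) table are *unclassifiable* — absence of
evidence, distinct from evidence of stability — and are reported separately
with a reason.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FractxError


def classify_export(
    wct_results: pd.DataFrame,
    cyt_results: pd.DataFrame,
    cyt_threshold: float = 3.0,
    wct_threshold: float = 3.0,
    require_cyt_p: bool = False,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify shared features as export inhibited / stimulated / none.

    Returns ``(calls, unclassifiable)``. ``calls`` has one row per feature
    present in both DE tables with columns ``log2fc_wct, log2fc_cyt, call``;
    ``unclassifiable`` lists features present in only one table with a
    ``reason`` column.
    """
    if cyt_threshold <= 1 or wct_threshold <= 1:
        raise FractxError("fold-change thresholds must exceed 1")
    shared = wct_results.index.intersection(cyt_results.index)
    if len(shared) == 0:
        raise FractxError("no features shared between whole-cell and cytoplasmic tables")
    wct = wct_results.loc[shared]
    cyt = cyt_results.loc[shared]
    cyt_cut = np.log2(cyt_threshold)
    wct_cut = np.log2(wct_threshold)
    stable = wct["log2fc"].abs() < wct_cut
    passed = (cyt["p"] < p_threshold) if require_cyt_p else pd.Series(True, index=shared)
    call = np.where(
        (cyt["log2fc"] > cyt_cut) & stable & passed,
        "export_stimulated",
        np.where((cyt["log2fc"] < -cyt_cut) & stable & passed, "export_inhibited", "none"),
    )
    calls = pd.DataFrame(
        {"log2fc_wct": wct["log2fc"], "log2fc_cyt": cyt["log2fc"], "call": call},
        index=shared.rename("feature_id"),
    )
    only_wct = wct_results.index.difference(cyt_results.index)
    only_cyt = cyt_results.index.difference(wct_results.index)
    unclassifiable = pd.DataFrame(
        {
            "reason": ["absent_from_cytoplasmic_table"] * len(only_wct)
            + ["absent_from_whole_cell_table"] * len(only_cyt)
        },
        index=only_wct.append(only_cyt).rename("feature_id"),
    )
    return calls, unclassifiable


def export_direction_summary(calls: pd.DataFrame) -> tuple[int, int, int]:
    """Counts of (inhibited, stimulated, none) calls; partitions the table."""
    if len(calls) == 0:
        return (0, 0, 0)
    vc = calls["call"].value_counts()
    n_inh = int(vc.get("export_inhibited", 0))
    n_stim = int(vc.get("export_stimulated", 0))
    n_none = int(vc.get("none", 0))
    if n_inh + n_stim + n_none != len(calls):
        raise FractxError("export calls contain values outside the known classes")
    return (n_inh, n_stim, n_none)
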