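"""ES↔IR switch analysis at shared 3' splice junctions across genotypes.

For every significant ES site in condition A (e.g. the mutant line under
compound), the replicate-averaged trifurcation PSIs in condition A and in
condition B (e.g. the wild-type line under the same compound) are tabulated.
A site "switches" when condition B shows strictly lower ES PSI and strictly
higher IR PSI than condition A — the exon-skipping outcome in A converts to
intron retention in B.  The waterfall view orders sites by descending ES PSI
in one condition and plots both conditions in that same order.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import SiteKey, format_site_key
from .psi import TrifurcationPSI

log = logging.getLogger("splicemod")


def build_switch_table(
    significant_es_sites: Iterable[SiteKey],
    trifurcation_a: Mapping[SiteKey, TrifurcationPSI],
    trifurcation_b: Mapping[SiteKey, TrifurcationPSI],
) -> pd.DataFrame:
    """One row per significant ES site with both conditions' ES and IR PSIs.

    Sites with undefined trifurcation PSI in either condition are excluded
    from the table (and hence from both numerator and denominator of the
    switch fraction); the exclusion count is logged.
    """
    rows = []
    n_excluded = 0
    for site in sorted(set(significant_es_sites)):
        ta = trifurcation_a.get(site)
        tb = trifurcation_b.get(site)
        if ta is None or tb is None or not ta.defined or not tb.defined:
            n_excluded += 1
            continue
        rows.append(
            {
                "site": format_site_key(site),
                "es_psi_A": ta.psi_es,
                "ir_psi_A": ta.psi_ir,
                "es_psi_B": tb.psi_es,
                "ir_psi_B": tb.psi_ir,
                # strict inequalities: exact ties are not switches
                "is_switch": (tb.psi_es < ta.psi_es) and (tb.psi_ir > ta.psi_ir),
            }
        )
    if n_excluded:
        log.info("switch table: excluded %d sites with undefined PSI", n_excluded)
    df = pd.DataFrame(
        rows, columns=["site", "es_psi_A", "ir_psi_A", "es_psi_B", "ir_psi_B", "is_switch"]
    )
    df.attrs["n_excluded"] = n_excluded
    return df


def waterfall_order(switch_table: pd.DataFrame, order_condition: str = "A") -> pd.DataFrame:
    """Order sites by descending ES PSI in one condition (ties by site key).

    Both conditions' panels use this single order; a ``rank`` column is
    added (0 = highest ES PSI).
    """
    col = f"es_psi_{order_condition}"
    if col not in switch_table.columns:
        raise ValueError(f"unknown condition {order_condition!r}")
    out = switch_table.sort_values(
        [col, "site"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = range(len(out))
    return out


def count_switches(switch_table: pd.DataFrame) -> tuple[int, int, float]:
    """(n_switch, n_total, fraction); fraction is NaN on an empty table."""
    n_total = len(switch_table)
    n_switch = int(switch_table["is_switch"].sum()) if n_total else 0
    fraction = n_switch / n_total if n_total else float("nan")
    return n_switch, n_total, fraction
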