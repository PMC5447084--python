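"""Alpha-diversity indices and gene-set overlap summaries.

Shannon entropy is reported in nats; Simpson-family indices are reported
in all three common forms (Gini-Simpson probability, inverse Simpson
effective number, and Simpson evenness = inverse Simpson / richness) so
a reader can match whichever convention a table used.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from pmenet.tables import FeatureTable


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), and Simpson-family indices.

    With relative abundances p_i:
    observed = #{p_i > 0}; shannon = -sum p_i ln p_i;
    gini_simpson = 1 - sum p_i^2; inverse_simpson = 1 / sum p_i^2;
    simpson_evenness = inverse_simpson / observed.
    All-zero samples are reported with NaN indices.
    """
    rows = []
    for sid in table.sample_ids:
        x = table.values[sid].to_numpy(dtype=float)
        total = x.sum()
        if total <= 0:
            rows.append(
                {
                    "sample_id": sid,
                    "observed_richness": 0,
                    "shannon": np.nan,
                    "gini_simpson": np.nan,
                    "inverse_simpson": np.nan,
                    "simpson_evenness": np.nan,
                }
            )
            continue
        p = x[x > 0] / total
        d2 = float((p**2).sum())
        observed = int((x > 0).sum())
        rows.append(
            {
                "sample_id": sid,
                "observed_richness": observed,
                "shannon": float(-(p * np.log(p)).sum()),
                "gini_simpson": 1.0 - d2,
                "inverse_simpson": 1.0 / d2,
                "simpson_evenness": 1.0 / d2 / observed,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def gene_set_overlap(sets: dict[str, set]) -> dict[str, pd.DataFrame]:
    """Shared and endemic gene counts among groups (e.g. soil types).

    For each unordered pair (A, B): shared = |A n B|, shared_pct =
    100 |A n B| / |A u B|. For each group A: endemic = |A minus the union
    of all other groups|, endemic_pct = 100 endemic / |A|. Percentages
    for empty groups are NaN.
    """
    if len(sets) < 2:
        raise ValueError("need at least two groups")
    pair_rows = []
    for a, b in combinations(sets, 2):
        inter = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        pair_rows.append(
            {
                "group_a": a,
                "group_b": b,
                "shared": inter,
                "shared_pct": 100.0 * inter / union if union else math.nan,
            }
        )
    group_rows = []
    for a in sets:
        others = set().union(*(sets[b] for b in sets if b != a))
        endemic = len(sets[a] - others)
        group_rows.append(
            {
                "group": a,
                "size": len(sets[a]),
                "endemic": endemic,
                "endemic_pct": 100.0 * endemic / len(sets[a]) if sets[a] else math.nan,
            }
        )
    return {
        "pairwise": pd.DataFrame(pair_rows).set_index(["group_a", "group_b"]),
        "per_group": pd.DataFrame(group_rows).set_index("group"),
    }
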