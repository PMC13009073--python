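"""Pathway over-representation by two-sided Fisher's exact tests.

Each of the nine pre-defined pathway groups is tested with a 2x2 table
``[[sig_in, notsig_in], [sig_out, notsig_out]]`` comparing significant vs
non-significant features inside and outside the pathway. The two-sided
p-value follows the minimum-likelihood convention — the sum of hypergeometric
probabilities of all tables no more probable than the observed one — which is
what both scipy and the major statistical packages compute. BH adjustment
(monotone step-up) runs across exactly the nine pathway tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .differential import bh_adjust
from .errors import InvalidArgumentError

__all__ = ["EnrichmentRow", "fisher_enrichment", "enrichment_from_counts", "table2_report"]


@dataclass
class EnrichmentRow:
    pathway: str
    sig_count: int
    notsig_count: int
    p_fisher: float
    p_bh: float = np.nan

    @property
    def total(self) -> int:
        return self.sig_count + self.notsig_count


def _fisher_two_sided(sig_in: int, notsig_in: int, sig_out: int, notsig_out: int) -> float:
    if sig_out + notsig_out == 0:
        # pathway contains every feature: no out-group to compare against
        import warnings

        warnings.warn("pathway contains all features; p defined as 1", stacklevel=3)
        return 1.0
    return float(fisher_exact([[sig_in, notsig_in], [sig_out, notsig_out]]).pvalue)


def enrichment_from_counts(
    counts: Sequence[tuple[str, int, int]], monotone: bool = True
) -> list[EnrichmentRow]:
    """Fisher + BH from per-pathway (name, sig, notsig) count triples."""
    if not counts:
        raise InvalidArgumentError("need at least one pathway")
    tot_sig = sum(c[1] for c in counts)
    tot_not = sum(c[2] for c in counts)
    rows = []
    for name, s, ns in counts:
        p = _fisher_two_sided(s, ns, tot_sig - s, tot_not - ns)
        rows.append(EnrichmentRow(str(name), int(s), int(ns), p))
    q = bh_adjust([r.p_fisher for r in rows], monotone=monotone)
    for r, qi in zip(rows, q):
        r.p_bh = float(qi)
    return rows


def fisher_enrichment(
    sig_flags: Mapping[str, bool] | pd.Series,
    pathways: Mapping[str, object] | pd.Series,
    monotone: bool = True,
) -> list[EnrichmentRow]:
    """Per-pathway enrichment of significant features.

    ``sig_flags`` maps feature_id -> bool (typically q_bh < 0.05 from the
    differential stage); ``pathways`` maps feature_id -> pathway group. Every
    feature must carry a pathway assignment.
    """
    sig = pd.Series(sig_flags).astype(bool)
    pw = pd.Series(pathways)
    if len(sig) == 0:
        raise InvalidArgumentError("need at least one feature")
    missing = sig.index.difference(pw.index)
    if len(missing):
        raise InvalidArgumentError(
            f"features without pathway assignment: {list(missing[:5])}"
        )
    pw = pw.loc[sig.index]
    counts = []
    for name in pw.drop_duplicates().tolist():  # first-appearance order
        in_path = pw == name
        counts.append(
            (str(name), int((sig & in_path).sum()), int((~sig & in_path).sum()))
        )
    return enrichment_from_counts(counts, monotone=monotone)


def table2_report(rows: Sequence[EnrichmentRow]) -> str:
    """Formatted enrichment summary: counts, raw and BH p, plus a checksum line."""
    if not rows:
        raise InvalidArgumentError("no enrichment rows to report")
    lines = ["pathway\tsig\tnotsig\ttotal\tp_fisher\tp_bh"]
    for r in rows:
        lines.append(
            f"{r.pathway}\t{r.sig_count}\t{r.notsig_count}\t{r.total}"
            f"\t{r.p_fisher:.3f}\t{r.p_bh:.3f}"
        )
    lines.append(f"# total_features\t{sum(r.total for r in rows)}")
    return "\n".join(lines)


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "sig_count": [r.sig_count for r in rows],
            "notsig_count": [r.notsig_count for r in rows],
            "total": [r.total for r in rows],
            "p_fisher": [r.p_fisher for r in rows],
            "p_bh": [r.p_bh for r in rows],
        }
    )


def write_enrichment_csv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    rows_to_frame(rows).to_csv(path, index=False, float_format="%.17g")


def read_enrichment_csv(path: str | Path) -> list[EnrichmentRow]:
    df = pd.read_csv(path)
    return [
        EnrichmentRow(
            str(r.pathway),
            int(r.sig_count),
            int(r.notsig_count),
            float(r.p_fisher),
            float(r.p_bh),
        )
        for r in df.itertuples(index=False)
    ]
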