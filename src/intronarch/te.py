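"""Transposable-element composition of genes and the length correlations.

TE coverage is computed on interval unions so split or duplicated
annotations never inflate a fraction; overlaps between classes are resolved
by the fixed priority retrotransposon > DNA transposon > helitron >
unclassified. The correlation test is the sample Pearson r with a two-sided
p-value from the t transform with n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, TE_CLASSES, TEAnnotation

logger = logging.getLogger("intronarch")


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cur_s, cur_e = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _subtract(intervals, blockers):
    """Parts of ``intervals`` not covered by ``blockers`` (both sorted unions)."""
    out = []
    for s, e in intervals:
        cur = s
        for bs, be in blockers:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class TEProfile:
    """TE composition of one gene."""

    taxon: str
    gene_id: str
    te_fraction: float  # percent of gene (or intron) length covered by TE union
    class_fractions: dict[str, float] = field(default_factory=dict)  # % of TE bp
    ltr_split: dict[str, float] = field(default_factory=dict)  # % of LTR bp

    def as_row(self) -> dict:
        row = {"taxon": self.taxon, "gene_id": self.gene_id, "te_fraction": self.te_fraction}
        for c in TE_CLASSES:
            row[f"pct_{c}"] = self.class_fractions.get(c, 0.0)
        for s in ("Gypsy", "Copia", "other"):
            row[f"pct_ltr_{s}"] = self.ltr_split.get(s, 0.0)
        return row


def te_profile(
    model: GeneModel,
    annotations: list[TEAnnotation],
    denominator: str = "gene",
) -> TEProfile:
    """TE fractions for one gene from annotations on its gene-local frame.

    ``denominator`` is ``"gene"`` (full gene length, the default) or
    ``"intron"`` (intronic length only). Annotations extending beyond the
    gene span are clipped with a warning.
    """
    gene_len = len(model.gene_seq)
    clipped: list[TEAnnotation] = []
    for a in annotations:
        s, e = max(0, a.start), min(gene_len, a.end)
        if (s, e) != (a.start, a.end):
            logger.warning("TE annotation (%d,%d) clipped to gene span", a.start, a.end)
        if e > s:
            clipped.append(TEAnnotation(a.target, s, e, a.te_class, a.superfamily, a.divergence))
    denom_len = gene_len if denominator == "gene" else sum(e - s for s, e in model.introns)
    all_ivs = [(a.start, a.end) for a in clipped]
    te_bp = _union_length(all_ivs)
    te_fraction = 100.0 * te_bp / denom_len if denom_len else 0.0

    # class attribution with fixed priority on inter-class overlaps
    class_bp: dict[str, int] = {}
    blockers: list[tuple[int, int]] = []
    for cls in TE_CLASSES:
        ivs = sorted((a.start, a.end) for a in clipped if a.te_class == cls)
        merged = _merge(ivs)
        free = _subtract(merged, blockers)
        class_bp[cls] = _union_length(free)
        blockers = _merge(blockers + merged)
    total_cls = sum(class_bp.values())
    class_fractions = {
        c: (100.0 * bp / total_cls if total_cls else 0.0) for c, bp in class_bp.items()
    }

    ltr_bp: dict[str, int] = {"Gypsy": 0, "Copia": 0, "other": 0}
    for key in ltr_bp:
        ivs = [
            (a.start, a.end)
            for a in clipped
            if a.te_class == "retrotransposon"
            and (a.superfamily == key if key != "other" else a.superfamily not in ("Gypsy", "Copia"))
        ]
        ltr_bp[key] = _union_length(ivs)
    total_ltr = sum(ltr_bp.values())
    ltr_split = {k: (100.0 * v / total_ltr if total_ltr else 0.0) for k, v in ltr_bp.items()}
    return TEProfile(model.taxon, model.gene_id, te_fraction, class_fractions, ltr_split)


def _merge(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value.

    p is computed from ``t = r * sqrt((n-2)/(1-r^2))`` referred to a
    t-distribution with n - 2 degrees of freedom. Constant vectors and
    n < 3 are errors (r undefined / p degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlation_report(
    profiles: list[TEProfile],
    length_table: pd.DataFrame,
    genome_sizes: dict[str, float] | None = None,
    exclude_zero_te: bool = False,
) -> pd.DataFrame:
    """Pearson tests of gene length vs TE fraction and vs genome size.

    Incomplete records are dropped pairwise with logged counts; a pair with
    fewer than 3 complete records is skipped with a warning. With
    ``exclude_zero_te`` the TE test is restricted to genes carrying any TE.
    """
    lt = length_table.set_index(["taxon", "gene_id"])
    rows = []

    def run(name: str, pairs: list[tuple[float, float]], n_dropped: int):
        if len(pairs) < 3:
            logger.warning("correlation %s skipped: only %d complete pairs", name, len(pairs))
            return
        try:
            r, p = pearson_correlation([a for a, _ in pairs], [b for _, b in pairs])
        except ValueError as exc:
            logger.warning("correlation %s skipped: %s", name, exc)
            return
        rows.append({"pair": name, "n": len(pairs), "n_dropped": n_dropped, "r": r, "p": p})

    pairs, dropped = [], 0
    for prof in profiles:
        key = (prof.taxon, prof.gene_id)
        if key in lt.index and not (exclude_zero_te and prof.te_fraction == 0.0):
            pairs.append((float(lt.loc[key, "gene_length"]), prof.te_fraction))
        else:
            dropped += 1
    label = "gene_length~te_fraction" + ("_nonzero" if exclude_zero_te else "")
    run(label, pairs, dropped)

    if genome_sizes:
        pairs, dropped = [], 0
        for (taxon, _), row in lt.iterrows():
            if taxon in genome_sizes:
                pairs.append((float(row["gene_length"]), float(genome_sizes[taxon])))
            else:
                dropped += 1
        run("gene_length~genome_size", pairs, dropped)
    return pd.DataFrame(rows, columns=["pair", "n", "n_dropped", "r", "p"])


def te_profile_table(profiles: list[TEProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in profiles])
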