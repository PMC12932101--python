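"""Serostatus stratification and paired format-discordance testing.

Two classification rules operate on the replicate-mean transduction at the
1/4 serum dilution (the strongest tested serum concentration):

* **pool_eligibility** — above 90% transduction the sample is labeled
  seronegative (eligible for a reference serum pool); at or below 90% it is
  ineligible.  The stringent threshold minimizes false negatives when
  building antibody-free control pools.
* **neutralization** — below 50% transduction the sample is neutralizing;
  at or above 50% it is non-neutralizing.

Both thresholds are strict inequalities; boundary values fall to the
conservative side (ineligible / non-neutralizing).

Samples classified under both assay formats (CSC and VSC) are compared in a
paired 2x2 table; the discordant fraction and an exact McNemar test (the
two-sided binomial sign test on the discordant pairs, with the doubling
rule capped at 1) quantify format disagreement.  Discordant counts in
practice are small, so the exact test is the default; the chi-square
approximation is available behind a flag for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import binom

from .normalize import TransductionCurve

RULES = ("pool_eligibility", "neutralization")
POOL_THRESHOLD = 90.0
NEUTRALIZATION_THRESHOLD = 50.0
CLASSIFICATION_DILUTION = Fraction(1, 4)

#: label order per rule; the first label is the "negative" (no-antibody) side
RULE_LABELS = {
    "pool_eligibility": ("seronegative", "ineligible"),
    "neutralization": ("non_neutralizing", "neutralizing"),
}


@dataclass(frozen=True)
class Classification:
    """One sample's label under one rule, format and serotype."""

    sample_id: str
    serotype: str
    format: str
    rule: str
    transduction_at_quarter: float
    label: str


@dataclass
class DiscordanceTable:
    """Paired CSC-vs-VSC 2x2 classification table with the McNemar test."""

    serotype: str
    rule: str
    labels: tuple          # row/col label order (CSC rows, VSC columns)
    counts: np.ndarray     # 2x2; counts[i, j] = #samples CSC label i, VSC label j
    discordant_fraction: float  # percent of samples off the diagonal
    p_value: float
    n: int


def classify(
    curve: TransductionCurve,
    rule: str,
    pool_threshold: float = POOL_THRESHOLD,
    neutralization_threshold: float = NEUTRALIZATION_THRESHOLD,
) -> Classification:
    """Classify one curve by its replicate-mean transduction at 1/4 dilution."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    point = curve.point_at(CLASSIFICATION_DILUTION)
    if point is None:
        raise ValueError(
            f"curve for sample {curve.sample_id!r} lacks the 1/4 dilution point"
        )
    t = point.mean_pct
    if rule == "pool_eligibility":
        label = "seronegative" if t > pool_threshold else "ineligible"
    else:
        label = "neutralizing" if t < neutralization_threshold else "non_neutralizing"
    return Classification(
        sample_id=curve.sample_id,
        serotype=curve.serotype,
        format=curve.format,
        rule=rule,
        transduction_at_quarter=t,
        label=label,
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value on the discordant cells.

    The binomial sign test: with n = b + c discordant pairs under the null
    each direction is equally likely; p = min(1, 2 * P(X <= min(b, c))).
    Zero discordant pairs give p = 1.
    """
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5)))


def discordance(csc, vsc, method: str = "exact") -> DiscordanceTable:
    """Tabulate CSC-vs-VSC label discordance for the same samples.

    Parameters
    ----------
    csc, vsc : lists of Classification
        Same sample set, same rule, same serotype, one list per format.
    method : {"exact", "asymptotic"}
        Exact binomial McNemar (default) or the chi-square approximation
        with continuity correction (via statsmodels).
    """
    by_id_csc = {cl.sample_id: cl for cl in csc}
    by_id_vsc = {cl.sample_id: cl for cl in vsc}
    if set(by_id_csc) != set(by_id_vsc):
        raise ValueError("CSC and VSC classification sample sets differ")
    if not by_id_csc:
        raise ValueError("empty classification lists")
    rules = {cl.rule for cl in csc} | {cl.rule for cl in vsc}
    serotypes = {cl.serotype for cl in csc} | {cl.serotype for cl in vsc}
    if len(rules) != 1 or len(serotypes) != 1:
        raise ValueError("classifications must share one rule and one serotype")
    rule, serotype = rules.pop(), serotypes.pop()
    bad = [cl for cl in csc if cl.format != "CSC"] + [
        cl for cl in vsc if cl.format != "VSC"
    ]
    if bad:
        raise ValueError("format labels do not match the argument order (CSC, VSC)")

    labels = RULE_LABELS[rule]
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((2, 2), dtype=int)
    for sid, cl_c in by_id_csc.items():
        counts[index[cl_c.label], index[by_id_vsc[sid].label]] += 1
    n = int(counts.sum())
    b, c = int(counts[0, 1]), int(counts[1, 0])
    if method == "exact":
        p = mcnemar_exact(b, c)
    elif method == "asymptotic":
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        p = float(sm_mcnemar(counts, exact=False, correction=True).pvalue)
    else:
        raise ValueError("method must be 'exact' or 'asymptotic'")
    return DiscordanceTable(
        serotype=serotype,
        rule=rule,
        labels=labels,
        counts=counts,
        discordant_fraction=100.0 * (b + c) / n,
        p_value=p,
        n=n,
    )


def classification_table(classifications) -> "pd.DataFrame":
    """Classifications as a flat table (one row per sample/format/rule)."""
    import pandas as pd

    rows = [
        {
            "sample_id": c.sample_id,
            "serotype": c.serotype,
            "format": c.format,
            "rule": c.rule,
            "transduction_at_quarter": c.transduction_at_quarter,
            "label": c.label,
        }
        for c in classifications
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "serotype",
            "format",
            "rule",
            "transduction_at_quarter",
            "label",
        ],
    )


def discordance_report(tables) -> str:
    """Plain-text summary of discordance tables, one block per serotype/rule."""
    lines = []
    for t in tables:
        lines.append(f"{t.serotype} — rule: {t.rule} (n = {t.n})")
        lines.append(f"  CSC \\ VSC        {t.labels[0]:>18} {t.labels[1]:>18}")
        for i, lab in enumerate(t.labels):
            lines.append(
                f"  {lab:<16} {t.counts[i, 0]:>18d} {t.counts[i, 1]:>18d}"
            )
        lines.append(
            f"  discordant: {t.discordant_fraction:.1f}%   "
            f"McNemar p = {t.p_value:.4g}"
        )
        lines.append("")
    return "\n".join(lines)
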