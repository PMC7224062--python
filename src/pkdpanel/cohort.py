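"""Cohort-level reporting: diagnostic yield, concordance, and statistics.

The yield table partitions probands the way diagnostic panels report them:
positives split by gene (PKD1 vs PKD2) and by truncating status within PKD1,
negatives split off VUS-only probands, with percentages on the denominators a
reader expects (positives over all, T/NT over PKD1 positives, gene split of
VUS-only over VUS-only). All printed percentages are rounded half-up.

The association tests are implemented from first principles — the chi-square
statistic as sum((O-E)^2/E) and the Fisher exact test by hypergeometric
enumeration for 2x2 tables — with the selection rule used in small diagnostic
cohorts: Fisher whenever an observed cell is below 5 (configurable to the
expected-count rule). One-way ANOVA uses the classical between/within
decomposition and reports group means so the genotype ordering is inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .varcall import round_half_up


def percent(count: int, denom: int, ndigits: int = 1) -> float:
    """100*count/denom rounded half-up; errors on a zero denominator."""
    if denom == 0:
        raise ValueError("zero denominator")
    return round_half_up(100.0 * count / denom, ndigits)


# ---------------------------------------------------------------------------
# Yield table
# ---------------------------------------------------------------------------

POSITIVE_LABELS = ("ADPKD-PKD1-T", "ADPKD-PKD1-NT", "ADPKD-PKD2")
KNOWN_LABELS = POSITIVE_LABELS + ("PKD-VUS-only", "negative")


def yield_table(records: pd.DataFrame, arms: Sequence[str] | None = None) -> pd.DataFrame:
    """Diagnostic-yield counts and percentages, overall and per cohort arm.

    ``records`` needs columns ``nosology`` (and optionally ``arm``). Output
    rows: positive, PKD1, PKD1-T, PKD1-NT, PKD2, negative, VUS-only and its
    gene split; columns n/% per scope. Denominators: positive and negative vs
    all; PKD1 and PKD2 vs positives; T/NT vs PKD1 positives; VUS gene split vs
    VUS-only probands.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    unknown = set(records["nosology"]) - set(KNOWN_LABELS)
    if unknown:
        raise ValueError(f"unknown nosology labels: {sorted(unknown)}")

    scopes: list[tuple[str, pd.DataFrame]] = [("all", records)]
    if arms is None and "arm" in records.columns:
        arms = list(dict.fromkeys(records["arm"]))
    for arm in arms or []:
        scopes.append((arm, records[records["arm"] == arm]))

    out: dict[str, dict[str, float]] = {}
    for scope, df in scopes:
        lab = df["nosology"]
        n = len(df)
        pkd1_t = int((lab == "ADPKD-PKD1-T").sum())
        pkd1_nt = int((lab == "ADPKD-PKD1-NT").sum())
        pkd2 = int((lab == "ADPKD-PKD2").sum())
        pkd1 = pkd1_t + pkd1_nt
        pos = pkd1 + pkd2
        vus = int((lab == "PKD-VUS-only").sum())
        neg = n - pos  # negatives include VUS-only probands (no causative variant)
        col: dict[str, float] = {
            "total": n,
            "positive_n": pos, "positive_pct": percent(pos, n) if n else math.nan,
            "pkd1_n": pkd1, "pkd1_pct": percent(pkd1, pos) if pos else math.nan,
            "pkd1_t_n": pkd1_t, "pkd1_t_pct": percent(pkd1_t, pkd1) if pkd1 else math.nan,
            "pkd1_nt_n": pkd1_nt, "pkd1_nt_pct": percent(pkd1_nt, pkd1) if pkd1 else math.nan,
            "pkd2_n": pkd2, "pkd2_pct": percent(pkd2, pos) if pos else math.nan,
            "negative_n": neg, "negative_pct": percent(neg, n) if n else math.nan,
            "vus_only_n": vus, "vus_only_pct": percent(vus, n) if n else math.nan,
        }
        out[scope] = col
    return pd.DataFrame(out)


def family_history_breakdown(records: pd.DataFrame) -> dict[str, float]:
    """Yield among probands without a family history of the disease.

    Needs boolean column ``family_history``; returns counts and the detection
    percentages among no-history probands (PKD1-or-PKD2 positives, PKD2 share).
    """
    no_fh = records[~records["family_history"].astype(bool)]
    n = len(no_fh)
    if n == 0:
        raise ValueError("no probands without family history")
    lab = no_fh["nosology"]
    pos = int(lab.isin(POSITIVE_LABELS).sum())
    pkd2 = int((lab == "ADPKD-PKD2").sum())
    return {
        "n_no_family_history": n,
        "no_family_history_pct": percent(n, len(records)),
        "positive_n": pos,
        "positive_pct": percent(pos, n),
        "pkd2_n": pkd2,
        "pkd2_pct": percent(pkd2, pos) if pos else math.nan,
    }


def multi_variant_rate(records: pd.DataFrame, onset_classes: Sequence[str] = ("VEO", "EO")
                       ) -> dict[str, float]:
    """Fraction of (early-onset) probands carrying more than one variant.

    Needs columns ``n_variants`` and ``onset_class``.
    """
    sel = records[records["onset_class"].isin(onset_classes)]
    n = len(sel)
    if n == 0:
        raise ValueError("no probands in the requested onset classes")
    multi = int((sel["n_variants"] >= 2).sum())
    return {"n": n, "multi_variant_n": multi, "multi_variant_pct": percent(multi, n)}


def variant_spectrum(variants: pd.DataFrame) -> pd.DataFrame:
    """Spectrum of distinct variants: novelty, truncating status, categories.

    ``variants`` needs columns ``gene``, ``novel`` (bool), ``truncating``
    (bool), ``category``, ``de_novo`` (bool, optional). Percentages are per
    column scope (all / per gene), rounded half-up to one decimal.
    """
    if len(variants) == 0:
        raise ValueError("empty variant table")
    scopes = [("all", variants)] + [(g, variants[variants["gene"] == g])
                                    for g in dict.fromkeys(variants["gene"])]
    rows: dict[str, dict[str, float]] = {}
    for scope, df in scopes:
        n = len(df)
        rec: dict[str, float] = {"n": n}
        if scope == "all":
            for g in dict.fromkeys(variants["gene"]):
                rec[f"share_{g}_pct"] = percent(int((variants["gene"] == g).sum()),
                                                len(variants))
        for name, mask in (
            ("novel", df["novel"].astype(bool)),
            ("truncating", df["truncating"].astype(bool)),
        ):
            rec[f"{name}_n"] = int(mask.sum())
            rec[f"{name}_pct"] = percent(int(mask.sum()), n) if n else math.nan
        if "de_novo" in df.columns:
            rec["de_novo_n"] = int(df["de_novo"].astype(bool).sum())
            rec["de_novo_pct"] = percent(rec["de_novo_n"], n) if n else math.nan
        for cat in ("P", "LP", "VUS", "H"):
            cnt = int((df["category"] == cat).sum())
            rec[f"{cat}_n"] = cnt
            rec[f"{cat}_pct"] = percent(cnt, n) if n else math.nan
        rows[scope] = rec
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance against a gold standard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    confirmed: int  # test positives confirmed by the gold standard
    unconfirmed: int  # test positives rejected by the gold standard (FP)
    missed: int  # gold positives the test did not call (FN)
    gold_negative_concordant: int | None  # TN, when a negative universe is known
    sensitivity_pct: int
    false_positive_rate_pct: int  # among test positives
    specificity_pct: int | None
    accuracy_pct: int | None


def concordance_metrics(
    test_positive: Iterable,
    gold_positive: Iterable,
    universe: Iterable | None = None,
) -> ConcordanceResult:
    """Sensitivity / FP-rate (and specificity/accuracy given a site universe).

    Sensitivity = confirmed / (confirmed + missed); the false-positive rate is
    reported among test positives (unconfirmed / all test positives), matching
    how confirmation workflows count their Sanger rejections. Percentages are
    rounded half-up to integers. Specificity and accuracy are computed only
    when the negative-site ``universe`` is supplied. An empty gold positive set
    is an error (sensitivity undefined).
    """
    t, g = set(test_positive), set(gold_positive)
    if not g:
        raise ValueError("empty gold-positive set: sensitivity undefined")
    confirmed = len(t & g)
    unconfirmed = len(t - g)
    missed = len(g - t)
    sens = int(round_half_up(100.0 * confirmed / (confirmed + missed), 0))
    fpr = int(round_half_up(100.0 * unconfirmed / len(t), 0)) if t else 0
    spec = acc = tn = None
    if universe is not None:
        u = set(universe)
        neg = u - g
        tn_set = neg - t
        tn = len(tn_set)
        spec = int(round_half_up(100.0 * tn / len(neg), 0)) if neg else None
        acc = int(round_half_up(100.0 * (confirmed + tn) / len(u), 0)) if u else None
    return ConcordanceResult(confirmed, unconfirmed, missed, tn, sens, fpr, spec, acc)


# ---------------------------------------------------------------------------
# Association tests (first principles)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    test: str  # "chi_square" | "fisher_exact"
    statistic: float | None
    p_value: float
    note: str = ""


def chi_square_statistic(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square statistic sum((O-E)^2/E) and degrees of freedom."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ValueError("zero expected count (empty row or column)")
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, dof


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose point
    probability does not exceed the observed one (with a small relative
    tolerance against floating-point ties).
    """
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2):
        raise ValueError("Fisher enumeration implemented for 2x2 tables")
    a, b = int(obs[0, 0]), int(obs[0, 1])
    c, d = int(obs[1, 0]), int(obs[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, n, c1, r1))
    total = 0.0
    for x in range(lo, hi + 1):
        p = float(stats.hypergeom.pmf(x, n, c1, r1))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def categorical_association(
    table: np.ndarray | Sequence[Sequence[int]],
    small_cell_rule: str = "observed",
    small_cell_threshold: int = 5,
) -> AssociationResult:
    """Chi-square or Fisher exact association for a contingency table.

    Fisher is selected iff any cell (observed counts by default; set
    ``small_cell_rule='expected'`` for the textbook rule) is below the
    threshold and the table is 2x2. A larger table with a small cell falls
    back to chi-square with a warning note.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 outcome levels")
    if small_cell_rule == "observed":
        small = bool((obs < small_cell_threshold).any())
    elif small_cell_rule == "expected":
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        small = bool((expected < small_cell_threshold).any())
    else:
        raise ValueError("small_cell_rule must be 'observed' or 'expected'")
    if small and obs.shape == (2, 2):
        return AssociationResult("fisher_exact", None, fisher_exact_2x2(obs))
    stat, dof = chi_square_statistic(obs)
    p = float(stats.chi2.sf(stat, dof))
    note = "small cell in non-2x2 table; chi-square approximation" if small else ""
    return AssociationResult("chi_square", stat, p, note)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    df_between: int
    df_within: int


def anova_onset(
    records: pd.DataFrame,
    age_field: str = "onset_age",
    group_field: str = "nosology",
    groups: Sequence[str] | None = None,
) -> AnovaResult:
    """One-way ANOVA of an age variable across genotype groups.

    Classical decomposition: F = (SSB/dfB) / (SSW/dfW). Group means are
    reported so the expected severity ordering (truncating PKD1 earliest) can
    be read directly. Groups with fewer than two non-missing observations are
    an error naming the group.
    """
    if groups is None:
        groups = list(dict.fromkeys(records[group_field]))
    samples: dict[str, np.ndarray] = {}
    for gname in groups:
        vals = records.loc[records[group_field] == gname, age_field].dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 observations")
        samples[gname] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    all_vals = np.concatenate(list(samples.values()))
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in samples.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    dfb = len(samples) - 1
    dfw = len(all_vals) - len(samples)
    if ssw == 0:
        f = 0.0 if ssb == 0 else math.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = float((ssb / dfb) / (ssw / dfw))
        p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(f, p, {g: float(v.mean()) for g, v in samples.items()},
                       {g: int(len(v)) for g, v in samples.items()}, dfb, dfw)
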