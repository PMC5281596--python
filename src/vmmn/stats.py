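"""Repeated-measures statistics and behavioural scoring.

The ANOVA machinery wraps :mod:`pingouin` (mixed and repeated-measures
decompositions) and normalises its output to one tidy table per design:
effect, sums of squares, F, uncorrected p, Greenhouse–Geisser epsilon
and corrected p for within effects with more than two levels, and
partial eta squared.  Post hoc comparisons use the Tukey HSD procedure
computed from cell means and the ANOVA error term via the studentized
range distribution.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats

from .exceptions import ConfigurationError, DesignError

ANOVA_COLUMNS = ["effect", "ss_effect", "ss_error", "df_num", "df_den", "F",
                 "p_uncorrected", "gg_epsilon", "p_gg", "partial_eta_sq"]


def greenhouse_geisser_epsilon(level_data: np.ndarray) -> float:
    """Sample Greenhouse–Geisser epsilon for a k-level within factor.

    ``level_data`` is (n_subjects, k).  Epsilon is
    ``(Σλ)² / ((k−1) Σλ²)`` over the eigenvalues of the double-centred
    covariance matrix of the factor levels; it lies in [1/(k−1), 1],
    equalling 1 under sphericity.
    """
    x = np.asarray(level_data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigurationError("need (n_subjects, k>=2) level data")
    k = x.shape[1]
    cov = np.cov(x, rowvar=False)
    centering = np.eye(k) - np.ones((k, k)) / k
    centred = centering @ cov @ centering
    eigvals = np.linalg.eigvalsh(centred)
    eigvals = eigvals[eigvals > 1e-12 * max(eigvals.max(), 1.0)]
    if eigvals.size == 0:
        return 1.0
    return float(eigvals.sum() ** 2 / ((k - 1) * (eigvals ** 2).sum()))


def _check_balanced(table: pd.DataFrame, dv: str, subject: str,
                    within: list[str], between: str | None) -> None:
    factors = list(within) + ([between] if between else [])
    if not factors:
        raise DesignError("no factors supplied")
    for f in factors:
        if table[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs at least two levels")
    if within:
        counts = table.groupby([subject] + list(within), observed=True)[dv].size()
        if counts.nunique() != 1 or counts.iloc[0] != 1:
            raise DesignError("design must have exactly one value per subject x cell")
        expected_cells = int(np.prod([table[f].nunique() for f in within]))
        per_subject_rows = table.groupby(subject, observed=True).size()
        if (per_subject_rows != expected_cells).any():
            raise DesignError("every subject must contribute every within cell")
    if between is not None:
        per_subject = table.groupby(subject, observed=True)[between].nunique()
        if (per_subject != 1).any():
            raise DesignError(f"subjects must belong to exactly one {between} group")
        sizes = table.drop_duplicates(subject).groupby(between, observed=True).size()
        if sizes.min() < 2:
            raise DesignError("need >= 2 subjects per group")
        if sizes.nunique() != 1:
            raise DesignError("unbalanced between-subject groups")


def _p_gg(F: float, df1: float, df2: float, eps: float) -> float:
    if not np.isfinite(F):
        return np.nan
    return float(sstats.f.sf(F, eps * df1, eps * df2))


def rm_anova(table: pd.DataFrame, dv: str, subject: str,
             within: list[str] | str | None = None,
             between: str | None = None) -> pd.DataFrame:
    """Repeated-measures / mixed ANOVA on a balanced long table.

    Parameters
    ----------
    table
        Long-format data with one row per subject × cell.
    dv, subject
        Column names of the response and the subject identifier.
    within
        One or two within-subject factor columns.
    between
        Optional between-subject factor column (e.g. age group).

    Returns
    -------
    DataFrame
        One row per effect with the ``ANOVA_COLUMNS`` layout (SS, dfs,
        F, uncorrected p, GG epsilon, corrected p, partial eta
        squared).  For within effects with more than two levels,
        ``p_gg`` is the p value at Greenhouse–Geisser-adjusted degrees
        of freedom; for two-level or purely between effects sphericity
        holds trivially and ``p_gg`` equals the uncorrected p.
    """
    within = [within] if isinstance(within, str) else list(within or [])
    if len(within) > 2:
        raise DesignError("at most two within factors are supported")
    _check_balanced(table, dv, subject, within, between)

    work = table.copy()
    if dv in (subject, between, *within):
        raise DesignError("dv column name collides with a factor column")

    # Degenerate data (no variance anywhere): every F is 0 by
    # convention and pingouin omits the F/p columns entirely.
    values = work[dv].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return _degenerate_table(work, subject, within, between)

    if between is not None and len(within) == 1:
        raw = pg.mixed_anova(data=work, dv=dv, within=within[0], subject=subject,
                             between=between, correction=True)
        return _normalize_mixed(raw, work, dv, subject, within[0], between)
    if between is not None and not within:
        raw = pg.anova(data=work.drop_duplicates([subject]), dv=dv,
                       between=between, detailed=True)
        return _normalize_between(raw, between)
    if between is None and within:
        if dv == "value":  # pingouin's two-way melt reserves this name
            work = work.rename(columns={dv: "_dv_"})
            dv = "_dv_"
        raw = pg.rm_anova(data=work, dv=dv, within=within if len(within) > 1 else within[0],
                          subject=subject, detailed=True, correction=True)
        return _normalize_within(raw, work, dv, subject, within)
    if between is not None and len(within) == 2:
        raise DesignError(
            "mixed designs with two within factors are outside the wrapper; "
            "analyse per group or per level"
        )
    raise DesignError("no analyzable design")


def _degenerate_table(data: pd.DataFrame, subject: str, within: list[str],
                      between: str | None) -> pd.DataFrame:
    n = data[subject].nunique()
    g = data[between].nunique() if between else 1
    resid_df = n - g if between else n - 1
    rows = []
    if between:
        rows.append(_row(between, 0.0, 0.0, g - 1, n - g, 0.0, 1.0, np.nan, 1.0, 0.0))
    kprod = 1
    for f in within:
        k = data[f].nunique()
        kprod *= k
        rows.append(_row(f, 0.0, 0.0, k - 1, (k - 1) * resid_df, 0.0, 1.0, 1.0, 1.0, 0.0))
    if between and len(within) == 1:
        k = data[within[0]].nunique()
        rows.append(_row(f"{between} * {within[0]}", 0.0, 0.0, (g - 1) * (k - 1),
                         (k - 1) * (n - g), 0.0, 1.0, 1.0, 1.0, 0.0))
    if not between and len(within) == 2:
        k1, k2 = (data[f].nunique() for f in within)
        rows.append(_row(f"{within[0]} * {within[1]}", 0.0, 0.0,
                         (k1 - 1) * (k2 - 1), (k1 - 1) * (k2 - 1) * (n - 1),
                         0.0, 1.0, 1.0, 1.0, 0.0))
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def _row(effect, ss_e, ss_err, df1, df2, F, p, eps, p_gg, np2) -> dict:
    return dict(zip(ANOVA_COLUMNS, [effect, ss_e, ss_err, df1, df2, F, p, eps,
                                    p_gg, np2]))


def _normalize_mixed(raw: pd.DataFrame, data: pd.DataFrame, dv: str,
                     subject: str, within: str, between: str) -> pd.DataFrame:
    raw = raw.set_index("Source")
    k = data[within].nunique()
    w = raw.loc[within]
    eps = float(w["eps"]) if np.isfinite(w["eps"]) else 1.0
    rows = []

    b = raw.loc[between]
    np2_b = float(b["np2"])
    ss_b = float(b["SS"])
    rows.append(_row(between, ss_b, _ss_error(ss_b, np2_b), float(b["DF1"]),
                     float(b["DF2"]), float(b["F"]), float(b["p_unc"]),
                     np.nan, float(b["p_unc"]), np2_b))

    np2_w = float(w["np2"])
    ss_w = float(w["SS"])
    p_gg = float(w["p_GG_corr"]) if "p_GG_corr" in w and np.isfinite(w.get("p_GG_corr", np.nan)) \
        else _p_gg(float(w["F"]), float(w["DF1"]), float(w["DF2"]), eps)
    if k <= 2:
        eps, p_gg = 1.0, float(w["p_unc"])
    rows.append(_row(within, ss_w, _ss_error(ss_w, np2_w), float(w["DF1"]),
                     float(w["DF2"]), float(w["F"]), float(w["p_unc"]),
                     eps, p_gg, np2_w))

    i = raw.loc["Interaction"]
    np2_i = float(i["np2"])
    ss_i = float(i["SS"])
    p_gg_i = float(i["p_unc"]) if k <= 2 else _p_gg(float(i["F"]), float(i["DF1"]),
                                                    float(i["DF2"]), eps)
    rows.append(_row(f"{between} * {within}", ss_i, _ss_error(ss_i, np2_i),
                     float(i["DF1"]), float(i["DF2"]), float(i["F"]),
                     float(i["p_unc"]), eps if k > 2 else 1.0, p_gg_i, np2_i))
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def _ss_error(ss_effect: float, np2: float) -> float:
    if np2 <= 0:
        return np.nan
    return ss_effect * (1.0 - np2) / np2


def _normalize_between(raw: pd.DataFrame, between: str) -> pd.DataFrame:
    raw = raw.set_index("Source")
    eff, err = raw.loc[between], raw.loc["Within"]
    ss_e, ss_err = float(eff["SS"]), float(err["SS"])
    np2 = ss_e / (ss_e + ss_err)
    return pd.DataFrame([_row(between, ss_e, ss_err, float(eff["DF"]),
                              float(err["DF"]), float(eff["F"]),
                              float(eff["p_unc"]), np.nan, float(eff["p_unc"]),
                              np2)], columns=ANOVA_COLUMNS)


def _normalize_within(raw: pd.DataFrame, data: pd.DataFrame, dv: str,
                      subject: str, within: list[str]) -> pd.DataFrame:
    rows = []
    if len(within) == 1:
        raw = raw.set_index("Source")
        eff, err = raw.loc[within[0]], raw.loc["Error"]
        k = data[within[0]].nunique()
        ss_e, ss_err = float(eff["SS"]), float(err["SS"])
        np2 = ss_e / (ss_e + ss_err)
        eps = float(eff["eps"]) if "eps" in eff and np.isfinite(eff["eps"]) else 1.0
        p_unc = float(eff["p_unc"])
        p_gg = p_unc if k <= 2 else (
            float(eff["p_GG_corr"]) if "p_GG_corr" in eff and np.isfinite(eff["p_GG_corr"])
            else _p_gg(float(eff["F"]), float(eff["DF"]), float(err["DF"]), eps)
        )
        rows.append(_row(within[0], ss_e, ss_err, float(eff["DF"]),
                         float(err["DF"]), float(eff["F"]), p_unc,
                         eps if k > 2 else 1.0, p_gg, np2))
        return pd.DataFrame(rows, columns=ANOVA_COLUMNS)

    # two-way within: pingouin reports effects only; reconstruct each
    # effect's error SS from MS_error = MS_effect / F.
    levels = {f: data[f].nunique() for f in within}
    for _, eff in raw.iterrows():
        name = str(eff["Source"])
        F = float(eff["F"])
        df1, df2 = float(eff["ddof1"]), float(eff["ddof2"])
        ss_e = float(eff["SS"])
        ms_e = float(eff["MS"])
        ss_err = (ms_e / F) * df2 if F > 0 else np.nan
        np2 = ss_e / (ss_e + ss_err) if np.isfinite(ss_err) else np.nan
        k_eff = np.prod([levels[f] for f in within if f in name]) or 2
        eps = float(eff["eps"]) if np.isfinite(eff["eps"]) else 1.0
        p_unc = float(eff["p_unc"])
        p_gg = p_unc if df1 <= 1 else (
            float(eff["p_GG_corr"]) if np.isfinite(eff.get("p_GG_corr", np.nan))
            else _p_gg(F, df1, df2, eps)
        )
        rows.append(_row(name, ss_e, ss_err, df1, df2, F, p_unc,
                         eps if df1 > 1 else 1.0, p_gg, np2))
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def format_effect(row: pd.Series | dict) -> str:
    """Report one effect in the field's conventional style:
    ``F(1,28) = 14.67, p < 0.001, ηp² = 0.34``."""
    p = row["p_gg"] if np.isfinite(row.get("p_gg", np.nan)) else row["p_uncorrected"]
    if p < 0.001:
        p_text = "p < 0.001"
    elif p < 0.01:
        p_text = "p < 0.01"
    elif p < 0.05:
        p_text = "p < 0.05"
    else:
        p_text = f"p = {p:.2f}"
    return (f"F({row['df_num']:g},{row['df_den']:g}) = {row['F']:.2f}, {p_text}, "
            f"ηp² = {row['partial_eta_sq']:.2f}")


def anova_report(table: pd.DataFrame) -> str:
    return "\n".join(f"{r['effect']}: {format_effect(r)}" for _, r in table.iterrows())


# ---------------------------------------------------------------------------
# Post hoc
# ---------------------------------------------------------------------------

def tukey_hsd(cell_means: dict | pd.Series, ms_error: float, df_error: float,
              n_per_cell: int) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from summary statistics.

    ``q = |m_i − m_j| / sqrt(MS_error / n)`` referred to the
    studentized range distribution with k groups and ``df_error``
    degrees of freedom.  Requires equal n per cell (balanced design).
    """
    if isinstance(cell_means, dict):
        cell_means = pd.Series(cell_means)
    if n_per_cell < 1 or ms_error < 0:
        raise ConfigurationError("need n_per_cell >= 1 and ms_error >= 0")
    k = len(cell_means)
    if k < 2:
        raise ConfigurationError("need at least two cells")
    se = math.sqrt(ms_error / n_per_cell)
    rows = []
    for a, b in itertools.combinations(cell_means.index, 2):
        diff = float(cell_means[a] - cell_means[b])
        q = abs(diff) / se if se > 0 else math.inf
        p = float(sstats.studentized_range.sf(q, k, df_error)) if se > 0 else 0.0
        if diff == 0.0:
            p = 1.0
        rows.append({"cell_a": a, "cell_b": b, "mean_diff": diff, "q": q, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavioural scoring
# ---------------------------------------------------------------------------

def score_hits(response_times: np.ndarray, task_events,
               response_window: tuple[float, float] = (200.0, 1000.0)) -> dict:
    """Hit rate for one sequence's frame-thickening task.

    A task event is hit when the first not-yet-consumed response falls
    within ``response_window`` ms after its onset; each response counts
    at most once.  Returns counts and the rate in percent.
    """
    lo, hi = response_window
    if not 0 <= lo < hi:
        raise ConfigurationError("invalid response window")
    responses = np.sort(np.asarray(response_times, dtype=float))
    used = np.zeros(len(responses), dtype=bool)
    hits = 0
    for ev in task_events:
        onset = getattr(ev, "onset", ev)
        in_window = (~used) & (responses >= onset + lo) & (responses <= onset + hi)
        idx = np.flatnonzero(in_window)
        if idx.size:
            used[idx[0]] = True
            hits += 1
    n = len(list(task_events))
    return {"n_events": n, "n_hits": hits,
            "hit_rate_percent": 100.0 * hits / n if n else np.nan}


def score_2afc(responses: pd.DataFrame,
               soa_levels: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Per-SOA proportion correct of a forced-choice session.

    Returns a frame with columns ``soa_ms, n_correct, n_trials,
    proportion``.  If ``soa_levels`` is given, unknown SOA values in the
    data raise a :class:`ConfigurationError`.
    """
    if not {"soa_ms", "correct"}.issubset(responses.columns):
        raise ConfigurationError("responses need columns soa_ms and correct")
    if soa_levels is not None:
        unknown = set(responses["soa_ms"].unique()) - set(soa_levels)
        if unknown:
            raise ConfigurationError(f"unknown SOA level(s) in data: {sorted(unknown)}")
    grouped = responses.groupby("soa_ms", observed=True)["correct"]
    out = grouped.agg(n_correct="sum", n_trials="size").reset_index()
    out["n_correct"] = out["n_correct"].astype(int)
    out["proportion"] = out["n_correct"] / out["n_trials"]
    return out
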