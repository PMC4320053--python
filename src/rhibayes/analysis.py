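"""Behavioral and electrodermal analyses of the two rubber-hand experiments.

Experiment 1 measures proprioceptive localization of the hidden left hand (40
responses before and 40 after the stimulation phase) and an ownership rating
(-3 strongly disagree … +3 strongly agree with "the rubber hand is my hand")
in four groups: synchronous stroking, asynchronous stroking, no stroking, and
a no-rubber-hand baseline.  Proprioceptive drift is the mean post-test minus
mean pre-test localization; positive values point toward the rubber hand.

Experiment 2 records skin conductance at 10 Hz in three groups (anatomically
plausible rubber arm, implausible hanging arm, no arm) and extracts an
event-related response at two time-points (first sight of the arm, and a
simulated threat to it): the maximum minus the minimum conductance within
1–5 s of the event, transformed as log10(SCR + 1).

All inferential statistics delegate to scipy/statsmodels; this module owns
the derived measures, exclusion rules and reporting conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Exp1Record",
    "Exp2Record",
    "DriftResult",
    "SchemaError",
    "DEFAULT_EXP1_COLUMNS",
    "DEFAULT_EXP2_COLUMNS",
    "load_exp1",
    "load_exp2",
    "exclude_outliers",
    "proprioceptive_drift",
    "drift_inference",
    "ownership_inference",
    "ownership_drift_correlation",
    "scr_response",
    "exp2_inference",
    "baseline_bias",
    "normality_screen",
    "sign_test",
]

EXP1_GROUPS = ("sync", "async", "no_stroke", "no_hand")
RUBBER_HAND_GROUPS = ("sync", "async", "no_stroke")
EXP2_GROUPS = ("plausible_arm", "hanging_arm", "no_arm")
EXP2_RATED_GROUPS = ("plausible_arm", "hanging_arm")


class SchemaError(ValueError):
    """Input table does not match the expected (or supplied) column mapping."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class Exp1Record:
    subject: str
    group: str
    pre: np.ndarray                      # localizations, mm
    post: np.ndarray                     # localizations, mm
    pre_ownership: int                   # -3 .. 3
    post_ownership: int                  # -3 .. 3
    true_hand_position: Optional[float] = None   # mm, if recorded

    def validate(self) -> None:
        if self.group not in EXP1_GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for subject {self.subject}")
        for name in ("pre", "post"):
            seq = np.asarray(getattr(self, name), dtype=float)
            if seq.size == 0:
                raise SchemaError(f"empty {name} localizations for subject {self.subject}")
            if seq.size != 40:
                warnings.warn(
                    f"subject {self.subject}: {name} has {seq.size} localizations "
                    "(expected 40)", stacklevel=2,
                )
        for name in ("pre_ownership", "post_ownership"):
            v = getattr(self, name)
            if not float(v).is_integer() or not (-3 <= v <= 3):
                raise SchemaError(
                    f"{name} must be an integer in [-3, 3], got {v!r} "
                    f"(subject {self.subject})"
                )


@dataclass
class Exp2Record:
    subject: str
    group: str
    times: np.ndarray                # s, 10 Hz grid
    conductance: np.ndarray          # microsiemens
    event_times: dict                # {"eye_opening": s, "threat": s}
    ownership: Optional[int] = None  # absent for the no-arm group

    def validate(self) -> None:
        if self.group not in EXP2_GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for subject {self.subject}")
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise SchemaError(f"trace too short for subject {self.subject}")
        dt = np.diff(t)
        if not np.allclose(dt, 0.1, atol=1e-6):
            raise SchemaError(
                f"trace of subject {self.subject} is not sampled at 10 Hz"
            )
        for name, ev in self.event_times.items():
            if not (t[0] <= ev <= t[-1]):
                raise SchemaError(
                    f"event {name!r} at {ev} s outside trace span for {self.subject}"
                )
        if self.ownership is not None and not (-3 <= int(self.ownership) <= 3):
            raise SchemaError(f"ownership out of range for subject {self.subject}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

DEFAULT_EXP1_COLUMNS = {
    "subject": "subject",
    "group": "group",
    "pre_prefix": "pre_",
    "post_prefix": "post_",
    "pre_ownership": "pre_ownership",
    "post_ownership": "post_ownership",
    "true_hand_position": "true_hand_position_mm",   # optional
}

DEFAULT_EXP2_COLUMNS = {
    "subject": "subject",
    "group": "group",
    "trace_file": "trace_file",
    "eye_opening": "eye_opening_s",
    "threat": "threat_s",
    "ownership": "ownership",      # may be blank for the no-arm group
    "time": "time_s",              # columns of the per-subject trace CSV
    "conductance": "conductance_uS",
}


def load_exp1(path, column_map: Optional[dict] = None) -> list[Exp1Record]:
    """Read an Experiment-1 table (one row per subject, wide localization
    columns ``pre_1..pre_k`` / ``post_1..post_k``)."""
    cmap = {**DEFAULT_EXP1_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("subject", "group", "pre_ownership", "post_ownership"):
        if cmap[key] not in df.columns:
            raise SchemaError(f"missing required column {cmap[key]!r}")
    pre_cols = _numbered_columns(df, cmap["pre_prefix"])
    post_cols = _numbered_columns(df, cmap["post_prefix"])
    if not pre_cols or not post_cols:
        raise SchemaError(
            f"no localization columns with prefixes {cmap['pre_prefix']!r} / "
            f"{cmap['post_prefix']!r}"
        )
    has_true = cmap["true_hand_position"] in df.columns
    records = []
    for i, row in df.iterrows():
        try:
            pre = row[pre_cols].to_numpy(dtype=float)
            post = row[post_cols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric localization in row {i}: {exc}") from exc
        true_pos = float(row[cmap["true_hand_position"]]) if has_true else None
        rec = Exp1Record(
            subject=str(row[cmap["subject"]]),
            group=str(row[cmap["group"]]),
            pre=pre[~np.isnan(pre)],
            post=post[~np.isnan(post)],
            pre_ownership=int(row[cmap["pre_ownership"]]),
            post_ownership=int(row[cmap["post_ownership"]]),
            true_hand_position=true_pos,
        )
        rec.validate()
        records.append(rec)
    return records


def _numbered_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in df.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def load_exp2(
    subjects_csv, traces_dir=None, column_map: Optional[dict] = None
) -> list[Exp2Record]:
    """Read an Experiment-2 cohort: a subjects table plus one trace CSV per
    subject (columns ``time_s, conductance_uS``), referenced by relative path."""
    cmap = {**DEFAULT_EXP2_COLUMNS, **(column_map or {})}
    subjects_csv = Path(subjects_csv)
    base = Path(traces_dir) if traces_dir is not None else subjects_csv.parent
    df = pd.read_csv(subjects_csv, float_precision="round_trip")
    for key in ("subject", "group", "trace_file", "eye_opening", "threat"):
        if cmap[key] not in df.columns:
            raise SchemaError(f"missing required column {cmap[key]!r}")
    records = []
    for i, row in df.iterrows():
        trace = pd.read_csv(
            base / str(row[cmap["trace_file"]]), float_precision="round_trip"
        )
        for key in ("time", "conductance"):
            if cmap[key] not in trace.columns:
                raise SchemaError(
                    f"trace for row {i} missing column {cmap[key]!r}"
                )
        own = row.get(cmap["ownership"])
        rec = Exp2Record(
            subject=str(row[cmap["subject"]]),
            group=str(row[cmap["group"]]),
            times=trace[cmap["time"]].to_numpy(dtype=float),
            conductance=trace[cmap["conductance"]].to_numpy(dtype=float),
            event_times={
                "eye_opening": float(row[cmap["eye_opening"]]),
                "threat": float(row[cmap["threat"]]),
            },
            ownership=None if pd.isna(own) else int(own),
        )
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# experiment 1: drift
# ---------------------------------------------------------------------------


def exclude_outliers(records: Sequence[Exp1Record], k: float = 3.0):
    """Exclude subjects whose mean pre-test localization deviates more than
    ``k`` sample SDs from the sample mean.

    Sample statistics are computed once on the full input; exclusions are not
    re-screened iteratively.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to screen for outliers")
    means = np.array([np.mean(r.pre) for r in records])
    center, sd = means.mean(), means.std(ddof=1)
    if sd == 0:
        kept, excluded = list(records), []
    else:
        z = np.abs(means - center) / sd
        kept = [r for r, zz in zip(records, z) if zz <= k]
        excluded = [r for r, zz in zip(records, z) if zz > k]
    if not kept:
        raise ValueError("outlier screening excluded every subject")
    return kept, excluded


def proprioceptive_drift(record: Exp1Record) -> float:
    """Mean post-test localization minus mean pre-test localization, mm.

    Positive drift points toward the rubber hand (toward the midline for the
    occluded left hand under the coordinate convention used here).
    """
    pre = np.asarray(record.pre, dtype=float)
    post = np.asarray(record.post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("empty localization sequence")
    return float(post.mean() - pre.mean())


def _cohens_d_one_sample(x: np.ndarray) -> float:
    return float(np.mean(x) / np.std(x, ddof=1))


def _cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2))
    return float((np.mean(a) - np.mean(b)) / sp)


@dataclass
class DriftResult:
    per_subject: pd.DataFrame        # subject, group, drift_mm
    per_group: dict                  # group -> {n, mean, t, df, p, d}
    anova: dict                      # {F, df_between, df_within, p}
    planned: dict                    # "sync_vs_<g>" -> {t, df, p_one_tailed, d}
    post_trend: dict                 # first-15 vs last-15 paired t across all subjects
    sign_convention: str = "positive = toward the rubber hand"


def _holm_adjust(entries: dict, key: str) -> None:
    """Attach Holm-adjusted p-values (in place) to a dict of planned
    comparisons.  Off by default everywhere: planned comparisons are
    reported unadjusted, matching the reporting convention of the analyses
    this pipeline mirrors."""
    from statsmodels.stats.multitest import multipletests

    names = list(entries)
    pvals = [entries[n][key] for n in names]
    adjusted = multipletests(pvals, method="holm")[1]
    for n, p_adj in zip(names, adjusted):
        entries[n][f"{key}_holm"] = float(p_adj)


def drift_inference(records: Sequence[Exp1Record], holm: bool = False) -> DriftResult:
    """Group-level drift statistics.

    Per group: two-tailed one-sample t against zero with Cohen's d
    (mean / SD).  Omnibus: one-way ANOVA over the four groups.  Planned
    comparisons: one-tailed independent t of sync against each of async,
    no-stroke and no-hand with pooled-SD Cohen's d.  A paired t of the first
    15 against the last 15 post-test localizations across all subjects checks
    that the drift does not dissipate over the post-test.
    """
    drifts = {g: [] for g in EXP1_GROUPS}
    rows = []
    for r in records:
        d = proprioceptive_drift(r)
        drifts.setdefault(r.group, []).append(d)
        rows.append({"subject": r.subject, "group": r.group, "drift_mm": d})
    # sorted per group so results are invariant to input row order
    drifts = {g: sorted(v) for g, v in drifts.items()}
    groups_present = [g for g in EXP1_GROUPS if len(drifts.get(g, [])) > 0]
    if len(groups_present) < 2 or any(len(drifts[g]) < 2 for g in groups_present):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    per_group = {}
    for g in groups_present:
        x = np.asarray(drifts[g])
        t, p = stats.ttest_1samp(x, 0.0)
        per_group[g] = {
            "n": len(x), "mean_mm": float(x.mean()),
            "t": float(t), "df": len(x) - 1, "p": float(p),
            "d": _cohens_d_one_sample(x),
        }
    arrays = [np.asarray(drifts[g]) for g in groups_present]
    F, p_anova = stats.f_oneway(*arrays)
    anova = {
        "F": float(F),
        "df_between": len(arrays) - 1,
        "df_within": sum(len(a) for a in arrays) - len(arrays),
        "p": float(p_anova),
    }
    planned = {}
    if "sync" in drifts and len(drifts["sync"]) >= 2:
        s = np.asarray(drifts["sync"])
        for g in ("async", "no_stroke", "no_hand"):
            if len(drifts.get(g, [])) < 2:
                continue
            o = np.asarray(drifts[g])
            t, p1 = stats.ttest_ind(s, o, alternative="greater")
            planned[f"sync_vs_{g}"] = {
                "t": float(t), "df": len(s) + len(o) - 2,
                "p_one_tailed": float(p1), "d": _cohens_d_pooled(s, o),
            }
    if holm and planned:
        _holm_adjust(planned, "p_one_tailed")
    first = np.array([np.mean(np.asarray(r.post)[:15]) for r in records])
    last = np.array([np.mean(np.asarray(r.post)[-15:]) for r in records])
    t_tr, p_tr = stats.ttest_rel(first, last)
    post_trend = {"t": float(t_tr), "df": len(records) - 1, "p": float(p_tr)}
    return DriftResult(
        per_subject=pd.DataFrame(rows),
        per_group=per_group,
        anova=anova,
        planned=planned,
        post_trend=post_trend,
    )


# ---------------------------------------------------------------------------
# experiment 1: ownership
# ---------------------------------------------------------------------------


def sign_test(values: Sequence[float], mu0: float = 0.0) -> dict:
    """Exact sign test of the median against ``mu0``: zeros dropped, exact
    two-sided binomial on the count of positive signs."""
    v = np.asarray(values, dtype=float) - mu0
    nonzero = v[v != 0]
    if nonzero.size == 0:
        raise ValueError("sign test undefined: no nonzero values")
    n_pos = int(np.sum(nonzero > 0))
    res = stats.binomtest(n_pos, nonzero.size, 0.5, alternative="two-sided")
    return {"n": int(nonzero.size), "n_positive": n_pos, "p": float(res.pvalue)}


def _median_test_two_groups(a, b) -> dict:
    """Independent-samples analog of the sign test: Mood's median test on the
    signs of responses relative to the pooled median."""
    res = stats.median_test(a, b)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "grand_median": float(res.median)}


def ownership_inference(records: Sequence[Exp1Record]) -> dict:
    """Ownership statistics.

    Pre-test ratings are pooled over the three groups that saw a rubber hand
    (before stimulation these groups are procedurally identical): fraction of
    positive ratings ("rated the rubber hand as their own"), median, and an
    exact sign test of the median against zero.  Change scores (post - pre)
    are compared across the three rubber-hand groups with a Kruskal-Wallis
    test and planned pairwise median comparisons (sync vs async, sync vs
    no-stroke).
    """
    pooled = [r.pre_ownership for r in records if r.group in RUBBER_HAND_GROUPS]
    if not pooled:
        raise ValueError("no rubber-hand-group records present")
    pooled = np.asarray(pooled, dtype=float)
    change = {
        g: np.asarray(
            [r.post_ownership - r.pre_ownership for r in records if r.group == g],
            dtype=float,
        )
        for g in RUBBER_HAND_GROUPS
    }
    out = {
        "pooled_pre": {
            "n": int(pooled.size),
            "fraction_positive": float(np.mean(pooled > 0)),
            "median": float(np.median(pooled)),
            "sign_test": sign_test(pooled),
        }
    }
    present = [g for g in RUBBER_HAND_GROUPS if change[g].size > 0]
    if len(present) == 3:
        H, p = stats.kruskal(*(change[g] for g in present))
        out["change_kruskal"] = {"H": float(H), "df": 2, "p": float(p)}
        out["change_pairwise"] = {
            "sync_vs_async": _median_test_two_groups(change["sync"], change["async"]),
            "sync_vs_no_stroke": _median_test_two_groups(
                change["sync"], change["no_stroke"]
            ),
        }
        out["change_median"] = {g: float(np.median(change[g])) for g in present}
    return out


def ownership_drift_correlation(
    records: Sequence[Exp1Record], phase: str = "post"
) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between the ownership rating of
    the given phase and proprioceptive drift, over the rubber-hand groups."""
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    recs = [r for r in records if r.group in RUBBER_HAND_GROUPS]
    if len(recs) < 3:
        raise ValueError("need at least 3 rubber-hand-group subjects")
    ratings = np.array(
        [r.pre_ownership if phase == "pre" else r.post_ownership for r in recs],
        dtype=float,
    )
    drift = np.array([proprioceptive_drift(r) for r in recs])
    if np.std(ratings) == 0 or np.std(drift) == 0:
        raise ValueError("zero variance in ratings or drift")
    r, p = stats.pearsonr(ratings, drift)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# experiment 2: skin conductance
# ---------------------------------------------------------------------------


def scr_response(
    times: Sequence[float],
    conductance: Sequence[float],
    event_time: float,
    window: tuple = (1.0, 5.0),
    log_base: float = 10.0,
) -> dict:
    """Event-related skin conductance response.

    Raw response: maximum minus minimum conductance over all samples with
    ``t`` in the closed interval ``[event + window[0], event + window[1]]``
    seconds (both endpoint samples included).  Transformed response:
    ``log(raw + 1)``, base 10 by default.  Both are returned.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conductance, dtype=float)
    lo, hi = event_time + window[0], event_time + window[1]
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(
            f"response window [{lo}, {hi}] s falls outside the trace "
            f"[{t[0]}, {t[-1]}] s"
        )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    seg = c[mask]
    raw = float(seg.max() - seg.min())
    return {"raw": raw, "transformed": float(np.log(raw + 1.0) / np.log(log_base))}


def _exp2_table(records: Sequence[Exp2Record], window=(1.0, 5.0), log_base=10.0):
    rows = []
    for r in records:
        row = {"subject": r.subject, "group": r.group, "ownership": r.ownership}
        for ev in ("eye_opening", "threat"):
            resp = scr_response(
                r.times, r.conductance, r.event_times[ev], window, log_base
            )
            row[f"scr_{ev}_raw"] = resp["raw"]
            row[f"scr_{ev}_log"] = resp["transformed"]
        rows.append(row)
    return pd.DataFrame(rows)


def exp2_inference(
    records: Sequence[Exp2Record], window=(1.0, 5.0), log_base=10.0,
    holm: bool = False,
) -> dict:
    """Experiment-2 statistics on transformed SCRs.

    Per time-point: one-way ANOVA over the three groups; planned two-tailed t
    of plausible-arm against each control with pooled-SD Cohen's d.
    Ownership: median, positive fraction and sign test per rated group, a
    between-group median comparison, and Pearson correlations of ownership
    with each time-point's transformed SCR over the two rated groups.
    """
    df = _exp2_table(records, window, log_base)
    present = [g for g in EXP2_GROUPS if (df.group == g).any()]
    if len(present) < 3:
        raise ValueError("need all three groups present")
    out = {"per_subject": df}
    for ev in ("eye_opening", "threat"):
        col = f"scr_{ev}_log"
        arrays = [df.loc[df.group == g, col].to_numpy() for g in EXP2_GROUPS]
        F, p = stats.f_oneway(*arrays)
        entry = {
            "anova": {
                "F": float(F),
                "df_between": 2,
                "df_within": len(df) - 3,
                "p": float(p),
            }
        }
        plaus = df.loc[df.group == "plausible_arm", col].to_numpy()
        for g in ("hanging_arm", "no_arm"):
            o = df.loc[df.group == g, col].to_numpy()
            t, pt = stats.ttest_ind(plaus, o)
            entry[f"plausible_vs_{g}"] = {
                "t": float(t), "df": len(plaus) + len(o) - 2,
                "p": float(pt), "d": _cohens_d_pooled(plaus, o),
            }
        if holm:
            _holm_adjust(
                {k: v for k, v in entry.items() if k != "anova"}, "p"
            )
        out[ev] = entry
    own = {}
    for g in EXP2_RATED_GROUPS:
        ratings = df.loc[df.group == g, "ownership"].dropna().to_numpy(dtype=float)
        if ratings.size:
            own[g] = {
                "n": int(ratings.size),
                "median": float(np.median(ratings)),
                "fraction_positive": float(np.mean(ratings > 0)),
                "sign_test": sign_test(ratings),
            }
    a = df.loc[df.group == "plausible_arm", "ownership"].dropna().to_numpy(dtype=float)
    b = df.loc[df.group == "hanging_arm", "ownership"].dropna().to_numpy(dtype=float)
    if a.size and b.size:
        own["plausible_vs_hanging"] = _median_test_two_groups(a, b)
    out["ownership"] = own
    rated = df[df.group.isin(EXP2_RATED_GROUPS)].dropna(subset=["ownership"])
    corr = {}
    for ev in ("eye_opening", "threat"):
        r, p = stats.pearsonr(
            rated["ownership"].to_numpy(dtype=float),
            rated[f"scr_{ev}_log"].to_numpy(),
        )
        corr[ev] = {"r": float(r), "p": float(p), "n": int(len(rated))}
    out["ownership_scr_correlation"] = corr
    return out


# ---------------------------------------------------------------------------
# baseline bias and normality screen
# ---------------------------------------------------------------------------


def baseline_bias(
    records: Sequence[Exp1Record], true_position: Optional[float] = None
) -> dict:
    """Pre-test localization bias toward the midline.

    Per subject: true hand position minus mean pre-test localization (so a
    localization short of the hand, i.e. toward the midline, is positive).
    Returns the mean bias, a one-sample t across subjects, and the mean of
    per-subject SDs of the pre-test responses.  If no true position is
    available the result says so explicitly instead of guessing one.
    """
    biases, sds = [], []
    for r in records:
        pos = r.true_hand_position if r.true_hand_position is not None else true_position
        if pos is None:
            return {"available": False,
                    "reason": "true hand position not recorded and not supplied"}
        biases.append(float(pos) - float(np.mean(r.pre)))
        sds.append(float(np.std(np.asarray(r.pre, dtype=float), ddof=1)))
    biases = np.asarray(biases)
    t, p = stats.ttest_1samp(biases, 0.0)
    return {
        "available": True,
        "n": len(biases),
        "mean_bias_mm": float(biases.mean()),
        "mean_within_subject_sd_mm": float(np.mean(sds)),
        "t": float(t),
        "df": len(biases) - 1,
        "p": float(p),
        "sign_convention": "positive = toward the midline",
    }


def normality_screen(
    records: Sequence[Exp1Record], alpha: float = 0.05, min_n: int = 8
) -> dict:
    """Fraction of subjects whose pre-test localization sample is *not*
    rejected at ``alpha`` by each of four normality tests: Shapiro-Wilk,
    Anderson-Darling, Jarque-Bera, and Lilliefors."""
    from statsmodels.stats.diagnostic import lilliefors

    passes = {t: 0 for t in ("shapiro_wilk", "anderson_darling", "jarque_bera", "lilliefors")}
    n_eval, flagged = 0, []
    for r in records:
        x = np.asarray(r.pre, dtype=float)
        if x.size < min_n or np.std(x) == 0:
            flagged.append(r.subject)
            continue
        n_eval += 1
        if stats.shapiro(x).pvalue > alpha:
            passes["shapiro_wilk"] += 1
        ad = stats.anderson(x, dist="norm")
        levels = np.asarray(ad.significance_level, dtype=float)
        crit = ad.critical_values[int(np.argmin(np.abs(levels - alpha * 100)))]
        if ad.statistic <= crit:
            passes["anderson_darling"] += 1
        if stats.jarque_bera(x).pvalue > alpha:
            passes["jarque_bera"] += 1
        if lilliefors(x, dist="norm")[1] > alpha:
            passes["lilliefors"] += 1
    if n_eval == 0:
        raise ValueError("no subject had enough localization samples to screen")
    return {
        "n_evaluated": n_eval,
        "flagged_subjects": flagged,
        "pass_fraction": {k: v / n_eval for k, v in passes.items()},
    }


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def exp1_report(records: Sequence[Exp1Record], outlier_k: float = 3.0) -> dict:
    """Full Experiment-1 analysis: outlier screen, drift and ownership
    inference, pre/post ownership-drift correlations, baseline bias and
    normality screen, as one JSON-serializable dictionary."""
    kept, excluded = exclude_outliers(records, k=outlier_k)
    drift = drift_inference(kept)
    r_post, p_post = ownership_drift_correlation(kept, "post")
    r_pre, p_pre = ownership_drift_correlation(kept, "pre")
    report = {
        "n_input": len(records),
        "n_excluded_outliers": len(excluded),
        "excluded_subjects": [r.subject for r in excluded],
        "drift": {
            "per_group": drift.per_group,
            "anova": drift.anova,
            "planned_one_tailed": drift.planned,
            "post_trend_first15_last15": drift.post_trend,
            "sign_convention": drift.sign_convention,
        },
        "ownership": ownership_inference(kept),
        "ownership_drift_correlation": {
            "post": {"r": r_post, "p": p_post},
            "pre": {"r": r_pre, "p": p_pre},
        },
        "baseline_bias": baseline_bias(kept),
        "normality_screen": normality_screen(kept),
    }
    report["_per_subject"] = drift.per_subject
    return report


def exp2_report(records: Sequence[Exp2Record]) -> dict:
    """Full Experiment-2 analysis as one JSON-serializable dictionary."""
    out = exp2_inference(records)
    out["n_input"] = len(records)
    out["_per_subject"] = out.pop("per_subject")
    return out


def report_to_json(report: dict, path) -> None:
    """Write a report dict to JSON; per-subject tables go to a sibling CSV."""
    report = dict(report)
    per_subject = report.pop("_per_subject", None)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if per_subject is not None:
        per_subject.to_csv(path.with_suffix(".per_subject.csv"), index=False)
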