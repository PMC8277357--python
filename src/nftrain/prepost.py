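"""Offline pre/post resting-state analysis.

Channels are grouped by cortical region (prefrontal, occipital, frontal,
central, parietal, the two pooled regions, and left/right temporal); each
group's PSD is the pointwise average of its member channels' PSDs; band
power is integrated from that average and analyzed as log₁₀ power. Pre
vs post is compared per band × group × condition with paired t-tests
(uncorrected p at α=.05, with a Benjamini–Hochberg adjusted column
appended). The same paired machinery serves arbitrary pre/post score
tables keyed by subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bands import BandDefinition, DEFAULT_BANDS
from .errors import CohortError, GroupingError, ZeroVarianceError
from .recording import CONDITIONS, Recording
from .spectral import EstimatorParams, PSDEstimate, compute_psd, band_power as _band_power

logger = logging.getLogger(__name__)

GROUP_LABELS: dict[int, str] = {
    1: "prefrontal",
    2: "occipital",
    3: "frontal",
    4: "central",
    5: "parietal",
    6: "prefrontal+frontal",
    7: "parietal+occipital",
    8: "temporal-left",
    9: "temporal-right",
}


@dataclass(frozen=True)
class ChannelGrouping:
    """Nine regional channel groups (id -> member channel names)."""

    groups: Mapping[int, tuple[str, ...]]
    labels: Mapping[int, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            object.__setattr__(self, "labels", dict(GROUP_LABELS))
        if set(self.groups) != set(range(1, 10)):
            raise GroupingError(
                f"expected exactly groups 1-9, got {sorted(self.groups)}"
            )
        for gid, members in self.groups.items():
            if not members:
                raise GroupingError(f"group {gid} is empty")

    def __getitem__(self, gid: int) -> tuple[str, ...]:
        return tuple(self.groups[gid])


def _default_grouping() -> ChannelGrouping:
    g1 = ("Fp1", "Fp2")
    g2 = ("PO7", "PO8", "Oz")
    g3 = ("F3", "Fz", "F4")
    g4 = ("C3", "Cz", "C4")
    g5 = ("P3", "Pz", "P4")
    return ChannelGrouping(groups={
        1: g1, 2: g2, 3: g3, 4: g4, 5: g5,
        6: g1 + g3, 7: g5 + g2, 8: ("T7",), 9: ("T8",),
    })


#: Regional groups over the default 16-channel montage. Group 6 pools the
#: prefrontal and frontal groups, group 7 the parietal and occipital ones.
DEFAULT_GROUPING: ChannelGrouping = _default_grouping()


@dataclass(frozen=True)
class PrePostResult:
    """Paired-t outcome for one band × group × condition cell."""

    band: str
    group: int
    condition: str
    n: int
    mean_change: float
    sd_diff: float
    t: float
    df: int
    p: float


def group_channels(
    montage: Sequence[str], grouping: ChannelGrouping = DEFAULT_GROUPING
) -> ChannelGrouping:
    """Validate a grouping against a montage; every member must exist."""
    if not montage:
        raise GroupingError("montage is empty")
    montage_set = set(montage)
    for gid, members in grouping.groups.items():
        missing = [m for m in members if m not in montage_set]
        if missing:
            raise GroupingError(
                f"channel not in montage: group {gid} names {missing}"
            )
    return grouping


def group_band_power(
    rec: Recording,
    group: Sequence[str],
    band: BandDefinition,
    params: EstimatorParams | None = None,
) -> float:
    """log₁₀ band power of the group-average PSD.

    Member channels' PSDs are averaged pointwise and the band integrated
    from the average — identical, by linearity, to averaging the channels'
    band powers.
    """
    if not group:
        raise GroupingError("empty group")
    missing = [ch for ch in group if ch not in rec.channels]
    if missing:
        raise GroupingError(f"channel not in montage: {missing}")
    psds = [compute_psd(rec.channels[ch], rec.fs, params) for ch in group]
    mean_density = np.mean([p.density for p in psds], axis=0)
    avg = psds[0].__class__(
        frequencies=psds[0].frequencies, density=mean_density,
        fs=rec.fs, params=psds[0].params,
    )
    return float(np.log10(_band_power(avg, band)))


def paired_t(
    pre: Sequence[float], post: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sided paired t-test on post − pre; returns (t, df, p).

    Computed from the difference-score formula t = mean(d)/(sd(d)/√n) with
    the tail probability from the t distribution (df = n − 1).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length (paired)")
    n = len(pre)
    if n < 2:
        raise ValueError("too few pairs: need n >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, n - 1, 1.0
        raise ZeroVarianceError("degenerate: zero variance with nonzero mean change")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def band_power_table(
    cohort: Iterable[Recording],
    grouping: ChannelGrouping = DEFAULT_GROUPING,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    params: EstimatorParams | None = None,
) -> pd.DataFrame:
    """Per-subject log₁₀ group band powers for every cell.

    Tidy frame with columns subject, phase, condition, band, group,
    log10_power — the input to ``prepost_report`` when starting from
    waveform recordings.
    """
    rows = []
    for rec in cohort:
        psds = {ch: compute_psd(x, rec.fs, params) for ch, x in rec.channels.items()}
        for gid, members in grouping.groups.items():
            missing = [ch for ch in members if ch not in psds]
            if missing:
                raise GroupingError(f"channel not in montage: {missing}")
            ref = psds[members[0]]
            avg = PSDEstimate(
                frequencies=ref.frequencies,
                density=np.mean([psds[ch].density for ch in members], axis=0),
                fs=rec.fs, params=ref.params,
            )
            for band in bands:
                rows.append((
                    rec.subject, rec.phase, rec.condition, band.name, gid,
                    float(np.log10(_band_power(avg, band))),
                ))
    return pd.DataFrame(
        rows,
        columns=["subject", "phase", "condition", "band", "group", "log10_power"],
    )


def cell_table_from_channel_powers(
    table: pd.DataFrame, grouping: ChannelGrouping = DEFAULT_GROUPING
) -> pd.DataFrame:
    """Collapse per-channel log powers to per-group cells.

    Accepts the tidy per-channel frame the cohort generator emits (columns
    subject, phase, condition, channel, band, log10_power). Group power is
    the log₁₀ of the mean linear power across member channels, matching the
    average-the-PSDs-then-integrate path.
    """
    rows = []
    lin = table.assign(power=10.0 ** table["log10_power"])
    for gid, members in grouping.groups.items():
        sub = lin[lin["channel"].isin(members)]
        agg = (
            sub.groupby(["subject", "phase", "condition", "band"], sort=True)["power"]
            .mean()
            .reset_index()
        )
        agg["group"] = gid
        agg["log10_power"] = np.log10(agg["power"])
        rows.append(agg.drop(columns="power"))
    return pd.concat(rows, ignore_index=True)


def prepost_report(
    cells: pd.DataFrame | Iterable[Recording],
    grouping: ChannelGrouping = DEFAULT_GROUPING,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    conditions: Sequence[str] = CONDITIONS,
    alpha: float = 0.05,
    params: EstimatorParams | None = None,
) -> pd.DataFrame:
    """Paired t-tests for every band × group × condition cell.

    `cells` is either a cohort of Recordings or an already-computed tidy
    cell table (subject/phase/condition/band/group/log10_power). Subjects
    missing any recording are excluded with a warning; fewer than 2 complete
    subjects aborts. Output columns: band, group, condition, n, mean_change,
    sd_diff, t, df, p, p_bh, significant.
    """
    if isinstance(cells, pd.DataFrame):
        table = cells
    else:
        table = band_power_table(cells, grouping, bands, params)

    # subjects must have both phases in every condition present
    complete = []
    for subj, sub in table.groupby("subject"):
        have = set(zip(sub["phase"], sub["condition"]))
        need = {(p, c) for p in ("pre", "post") for c in conditions}
        if need <= have:
            complete.append(subj)
        else:
            logger.warning("excluding subject %s: missing recordings", subj)
    if len(complete) < 2:
        raise CohortError("fewer than 2 complete subjects")
    table = table[table["subject"].isin(complete)]

    band_names = sorted(table["band"].unique())
    group_ids = sorted(table["group"].unique())
    results = []
    wide = table.pivot_table(
        index=["band", "group", "condition", "subject"],
        columns="phase", values="log10_power", aggfunc="mean",
    )
    for band in band_names:
        for gid in group_ids:
            for cond in conditions:
                try:
                    cell = wide.loc[(band, gid, cond)]
                except KeyError:
                    continue
                cell = cell.dropna()
                t, df, p = paired_t(cell["pre"].to_numpy(), cell["post"].to_numpy())
                diff = cell["post"] - cell["pre"]
                results.append({
                    "band": band, "group": gid, "condition": cond,
                    "n": len(cell), "mean_change": float(diff.mean()),
                    "sd_diff": float(diff.std(ddof=1)),
                    "t": t, "df": df, "p": p,
                })
    out = pd.DataFrame(results)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out


def score_table_compare(
    pre: pd.DataFrame, post: pd.DataFrame, subject_col: str = "subject_id"
) -> pd.DataFrame:
    """Per-measure paired comparison of two subject × measure score tables.

    Tables are aligned on `subject_col`; each shared numeric column is
    tested with a paired t-test on pairwise-complete rows. Output columns:
    measure, n, mean_change, sd_diff, t, df, p (NaN statistics for measures
    with fewer than 2 complete pairs).
    """
    if subject_col in pre.columns:
        pre = pre.set_index(subject_col)
    if subject_col in post.columns:
        post = post.set_index(subject_col)
    measures = [c for c in pre.columns if c in post.columns]
    if not measures:
        raise ValueError("no shared measure columns")
    shared = pre.index.intersection(post.index)
    rows = []
    for m in measures:
        a = pd.to_numeric(pre.loc[shared, m], errors="coerce")
        b = pd.to_numeric(post.loc[shared, m], errors="coerce")
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        if n < 2:
            rows.append({"measure": m, "n": n, "mean_change": np.nan,
                         "sd_diff": np.nan, "t": np.nan, "df": np.nan, "p": np.nan})
            continue
        t, df, p = paired_t(a[ok].to_numpy(), b[ok].to_numpy())
        d = (b[ok] - a[ok])
        rows.append({"measure": m, "n": n, "mean_change": float(d.mean()),
                     "sd_diff": float(d.std(ddof=1)), "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)
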