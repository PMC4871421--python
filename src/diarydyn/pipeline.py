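"""Per-patient analysis orchestration and cohort aggregation.

``analyze_patient`` runs the full per-patient procedure: imputation,
stationary-window determination on the focus pair, per-pair ADF screening,
lag selection, fitting with the diagnostic re-estimation loop, Granger
tests in both directions, ordering choice, IRF/OIRF with bootstrap bands,
accumulated IRF, FEVD, linear trends and windowed same-day correlations.
Pairs or patients that cannot be analysed are carried through with an
exclusion reason, never silently dropped.

``analyze_cohort`` aggregates patient reports into a causal-findings table
(one row per significant direction) and a per-patient trend table with
group summary percentages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import causality_dynamics as cd
from . import descriptives as desc
from . import var_core
from .diary_io import DiaryDataset, impute_missing
from .errors import DiaryDynError, ImputationError
from .stationarity import AnalysisWindow, find_stationary_window, screen_items

logger = logging.getLogger(__name__)

FOCUS_ITEM = "emotional_intolerance"
CO_FOCUS_ITEM = "restraint"


@dataclass
class PipelineConfig:
    """Every tolerance and tuning knob of the per-patient procedure."""

    alpha: float = 0.05
    T_min: int = 30
    step: int = 7
    adf_variant: str = "c"
    adf_max_lags: int | None = None
    p_max: int | None = None          # default: min(10, T_w // 10)
    portmanteau_h: int | None = None  # default: min(16, T_w // 4)
    H: int = 10
    B: int = 1000
    band_method: str = "hall"
    focus_item: str = FOCUS_ITEM
    co_focus_item: str = CO_FOCUS_ITEM
    impute_noise: bool = False
    max_missing_frac: float = 0.25
    trends_on_raw: bool = False
    seed: int = 0
    #: per-patient (start_day, end_day) overrides, keyed by patient_id
    window_overrides: dict[str, tuple[int, int]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a YAML (or JSON) config file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DiaryDynError(f"unknown config keys: {sorted(unknown)}")
        if "window_overrides" in raw:
            raw["window_overrides"] = {
                str(k): (int(v[0]), int(v[1]))
                for k, v in raw["window_overrides"].items()
            }
        return cls(**raw)


@dataclass
class PairResult:
    """Everything the report prints for one focus-item pairing."""

    focus: str
    partner: str
    excluded: bool = False
    exclusion_reason: str | None = None
    order: int | None = None
    lag_selection: dict | None = None
    diagnostics: dict | None = None
    granger: dict[str, cd.GrangerResult] = field(default_factory=dict)
    ordering: tuple[str, ...] | None = None
    significant_coefficients: list[dict] = field(default_factory=list)
    #: accumulated responses at the final horizon, plain and orthogonalised,
    #: keyed "<impulse>-><response>"
    accumulated_irf: dict[str, float] = field(default_factory=dict)
    accumulated_oirf: dict[str, float] = field(default_factory=dict)
    #: band-significant horizons of the cross responses (orthogonalised)
    significant_horizons: dict[str, list[int]] = field(default_factory=dict)
    fevd_share: dict[str, float] = field(default_factory=dict)
    same_day: desc.CorrelationResult | None = None
    adjustment_trail: list[dict] = field(default_factory=list)


@dataclass
class PatientReport:
    patient_id: str
    group: str
    T: int
    excluded: bool = False
    exclusion_reason: str | None = None
    window: AnalysisWindow | None = None
    n_imputed: int = 0
    trends: dict[str, desc.TrendResult] = field(default_factory=dict)
    pairs: list[PairResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return _to_jsonable(self)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _to_jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not k.startswith("_")
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _pair_seed(base: int, patient_id: str, partner: str) -> int:
    """Stable per-pair bootstrap seed derived from the config seed."""
    tag = zlib.crc32(f"{patient_id}/{partner}".encode())
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0])


def _analyze_pair(
    d: DiaryDataset,
    window: AnalysisWindow,
    focus: str,
    partner: str,
    cfg: PipelineConfig,
) -> PairResult:
    res = PairResult(focus=focus, partner=partner)
    y = np.column_stack(
        [window.slice(d.series(focus)), window.slice(d.series(partner))]
    )
    items = (focus, partner)
    T_w = window.length
    p_max = cfg.p_max or var_core.default_p_max(T_w)
    h = cfg.portmanteau_h or var_core.default_portmanteau_h(T_w)
    try:
        selection = var_core.select_lag_order(y, p_max)
        res.lag_selection = {
            "by_criterion": selection.by_criterion,
            "consensus": selection.consensus,
            "p_max": selection.p_max,
        }
        model, diag, trail = var_core.fit_with_adjustment(
            y, selection, p_max=p_max, h=h, alpha=cfg.alpha,
            items=items, window=window,
        )
    except DiaryDynError as e:
        res.excluded = True
        res.exclusion_reason = f"{type(e).__name__}: {e}"
        return res
    res.order = model.k
    res.adjustment_trail = trail
    res.diagnostics = {
        "stable": diag.stable,
        "max_eigenvalue_modulus": float(diag.eigenvalue_moduli.max()),
        "portmanteau_statistic": diag.portmanteau_statistic,
        "portmanteau_df": diag.portmanteau_df,
        "portmanteau_p": diag.portmanteau_p,
    }

    g_fp = cd.granger_test(model, focus, partner, alpha=cfg.alpha)
    g_pf = cd.granger_test(model, partner, focus, alpha=cfg.alpha)
    res.granger = {f"{focus}->{partner}": g_fp, f"{partner}->{focus}": g_pf}
    res.ordering = cd.choose_ordering(g_fp, g_pf, default=items)
    res.significant_coefficients = model.significant_coefficients(cfg.alpha)

    seed = _pair_seed(cfg.seed, d.patient_id, partner)
    plain = cd.compute_irf(model, H=cfg.H)
    orth = cd.compute_dynamics(
        model, H=cfg.H, orthogonalized=True, ordering=res.ordering,
        B=cfg.B, alpha=cfg.alpha, seed=seed, method=cfg.band_method,
    )
    fe = cd.fevd(model, H=cfg.H, ordering=res.ordering)
    for imp, resp in ((focus, partner), (partner, focus)):
        key = f"{imp}->{resp}"
        i, mm = items.index(resp), items.index(imp)
        res.accumulated_irf[key] = float(plain.accumulated_irf[-1, i, mm])
        res.accumulated_oirf[key] = float(orth.accumulated_irf[-1, i, mm])
        res.fevd_share[key] = fe.share(resp, imp)
        assert orth.bands is not None
        res.significant_horizons[key] = [
            hh for hh in range(cfg.H + 1) if orth.bands.significant_at(hh, i, mm)
        ]
    res.same_day = desc.same_day_correlation(
        d.series(focus), d.series(partner), window=window,
        items=items, alpha=cfg.alpha,
    )
    return res


def analyze_patient(
    d: DiaryDataset, cfg: PipelineConfig | None = None
) -> PatientReport:
    """Run the complete per-patient procedure; never raises on exclusions.

    The stationary window is determined on the focus pair (emotional
    intolerance with restraint); other items are ADF-screened on that
    window and excluded from pairing when nonstationary.  Linear trends are
    computed on the full participation period, same-day correlations on the
    analysis window.
    """
    cfg = cfg or PipelineConfig()
    report = PatientReport(patient_id=d.patient_id, group=d.group, T=d.T)

    if cfg.focus_item not in d.items:
        report.excluded = True
        report.exclusion_reason = f"focus item {cfg.focus_item!r} absent"
        return report

    raw = d
    try:
        d, imp = impute_missing(
            d, add_noise=cfg.impute_noise, seed=cfg.seed,
            max_missing_frac=cfg.max_missing_frac,
        )
        report.n_imputed = imp.total_imputed
    except ImputationError as e:
        report.excluded = True
        report.exclusion_reason = f"ImputationError: {e}"
        return report

    trend_source = raw if cfg.trends_on_raw else d
    for it in d.items:
        try:
            report.trends[it] = desc.linear_trend(
                trend_source.series(it), item=it, alpha=cfg.alpha
            )
        except DiaryDynError as e:
            logger.warning("%s: trend for %s failed: %s", d.patient_id, it, e)

    co_focus = cfg.co_focus_item if cfg.co_focus_item in d.items else None
    focus_pair = [cfg.focus_item] + ([co_focus] if co_focus else [])
    if d.patient_id in cfg.window_overrides:
        s, e = cfg.window_overrides[d.patient_id]
        window = AnalysisWindow(s, e, tuple(focus_pair))
    else:
        try:
            window = find_stationary_window(
                d, focus_pair, step=cfg.step, alpha=cfg.alpha,
                T_min=cfg.T_min, variant=cfg.adf_variant,
                max_lags=cfg.adf_max_lags,
            )
        except DiaryDynError as e:
            report.excluded = True
            report.exclusion_reason = f"{type(e).__name__}: {e}"
            return report
    report.window = window

    partners = [it for it in d.items if it != cfg.focus_item]
    screen = screen_items(
        d, window, partners, alpha=cfg.alpha,
        variant=cfg.adf_variant, max_lags=cfg.adf_max_lags,
    )
    for partner in partners:
        if not screen[partner]:
            report.pairs.append(
                PairResult(
                    focus=cfg.focus_item, partner=partner, excluded=True,
                    exclusion_reason="nonstationary on the analysis window",
                )
            )
            continue
        report.pairs.append(
            _analyze_pair(d, window, cfg.focus_item, partner, cfg)
        )
    return report


def causal_table(reports: Sequence[PatientReport], alpha: float = 0.05) -> pd.DataFrame:
    """One row per significant Granger direction, Table-4 shaped."""
    rows = []
    for rep in reports:
        for pair in rep.pairs:
            if pair.excluded:
                continue
            for key, g in pair.granger.items():
                if not g.significant:
                    continue
                rows.append(
                    {
                        "patient_id": rep.patient_id,
                        "group": rep.group,
                        "window_start": rep.window.start_day if rep.window else None,
                        "window_end": rep.window.end_day if rep.window else None,
                        "cause": g.cause,
                        "effect": g.effect,
                        "order": pair.order,
                        "F": g.F,
                        "df1": g.df1,
                        "df2": g.df2,
                        "p": g.p_value,
                        "significant_coefficients": "; ".join(
                            f"{c['estimate']:+.2f} (t-{c['lag']})"
                            for c in pair.significant_coefficients
                            if c["equation"] == g.effect
                            and c["regressor"] == g.cause
                        ),
                        "acc_irf_10d": pair.accumulated_irf.get(key),
                        "acc_oirf_10d": pair.accumulated_oirf.get(key),
                        "explained_variance_10d_pct": 100.0
                        * pair.fevd_share.get(key, np.nan),
                        "same_day_r": (
                            pair.same_day.r
                            if pair.same_day and pair.same_day.significant
                            else None
                        ),
                    }
                )
    cols = [
        "patient_id", "group", "window_start", "window_end", "cause", "effect",
        "order", "F", "df1", "df2", "p", "significant_coefficients",
        "acc_irf_10d", "acc_oirf_10d", "explained_variance_10d_pct", "same_day_r",
    ]
    return pd.DataFrame(rows, columns=cols)


def trend_table(reports: Sequence[PatientReport]) -> pd.DataFrame:
    """Per-patient trend coefficients plus group summary rows, Table-3 shaped."""
    items: list[str] = []
    for rep in reports:
        for it in rep.trends:
            if it not in items:
                items.append(it)
    rows = []
    order = {g: i for i, g in enumerate(("HSS", "LSS"))}
    for rep in sorted(reports, key=lambda r: (order.get(r.group, 9), r.patient_id)):
        row: dict = {"patient_id": rep.patient_id, "group": rep.group, "T": rep.T}
        for it in items:
            tr = rep.trends.get(it)
            row[it] = tr.beta if tr else np.nan
            row[f"{it}_significant"] = tr.significant if tr else False
        rows.append(row)

    results = {
        r.patient_id: r.trends for r in reports if r.trends
    }
    groups = {r.patient_id: r.group for r in reports}
    if results:
        summary = desc.cohort_trend_summary(results, groups).reset_index()
        for _, s in summary.iterrows():
            rows.append(
                {
                    "patient_id": f"{s['group']}: % sign. trends "
                    f"(neg. {s['pct_significant_negative']:.1f})",
                    "group": s["group"],
                    s["item"]: s["pct_significant"],
                }
            )
    return pd.DataFrame(rows)


def cohort_percentages(reports: Sequence[PatientReport]) -> dict[str, float]:
    """Per group, percent of patients with >= 1 significant Granger direction."""
    pct: dict[str, float] = {}
    for g in ("HSS", "LSS"):
        members = [r for r in reports if r.group == g]
        if not members:
            continue
        with_sig = {
            r.patient_id
            for r in members
            for p in r.pairs
            if not p.excluded and any(gr.significant for gr in p.granger.values())
        }
        pct[g] = 100.0 * len(with_sig) / len(members)
    return pct


def analyze_cohort(
    datasets: Sequence[DiaryDataset], cfg: PipelineConfig | None = None
) -> dict:
    """Analyse every dataset and aggregate the cohort tables.

    Returns a dict with ``reports`` (list of PatientReport), ``causal``
    and ``trends`` DataFrames and per-group percentages of patients with
    at least one significant Granger direction.
    """
    cfg = cfg or PipelineConfig()
    reports = [analyze_patient(d, cfg) for d in datasets]
    causal = causal_table(reports, alpha=cfg.alpha)
    pct = cohort_percentages(reports)
    return {
        "reports": reports,
        "causal": causal,
        "trends": trend_table(reports),
        "pct_patients_with_significant_pair": pct,
    }


def save_report(report: PatientReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
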