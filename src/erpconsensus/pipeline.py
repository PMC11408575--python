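"""Pipeline orchestration: from epoched trials to per-subject ERP windows.

Stages, per subject and condition:

1. *Method screening* — candidate base methods are vetted on the subject's
   temporally concatenated ERP (conditions stacked along time): a method is
   kept when the window it recovers has inner similarity above
   ``mn_innersim_thr`` and duration above ``mn_duration_ms`` in every
   condition (stochastic methods must pass in a majority of seeded repeats).
   When fewer than two methods survive, a replacement list screened on the
   group-average ERP is used instead.
2. *Trial selection* — each trial is consensus-clustered (all surviving
   methods, then NMI-selection) and kept when a window matching the template
   can be determined; the spatial-correlation threshold decrements from 0.70
   to 0.50 until at least half the trials survive, after which the
   inner-similarity threshold relaxes the same way.
3. *Across-trial consensus* — the retained trials' labelings are combined
   into the subject/condition labeling.
4. *Time-window determination* — contiguous cluster maps overlapping the
   template's search interval are filtered by inner similarity and template
   correlation (with stepwise relaxation), thin maps (< 10 ms) having first
   been absorbed into a correlated neighbour; the best candidate (highest
   correlation, then longer, then earlier) becomes the component's window.
5. *Scoring* — window bounds, inner similarity, mean amplitude at the
   component's site, and spatial correlation to the template, on the subject
   ERP and on every retained trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import METHOD_NAMES, STOCHASTIC_METHODS, ClusteringError, \
    cluster_epoch, derive_seed
from .consensus import consensus_across_trials, consensus_within_trial
from .datamodel import EpochSet, Labeling, PipelineConfig, ScoreRow, \
    TemplateMap, TimeWindow
from .metrics import inner_similarity, mean_topography, spatial_correlation, \
    window_amplitude

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SubjectResult",
    "segments",
    "merge_thin_maps",
    "determine_time_window",
    "score_window",
    "mn_select_methods",
    "estimate_optimal_k",
    "derive_template",
    "select_trials",
    "cluster_trials",
    "run_study",
    "grand_average",
]


@dataclass
class Segment:
    """Maximal run of identical cluster labels."""

    label: int
    start_idx: int
    end_idx: int
    start_ms: float
    end_ms: float

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def sl(self) -> slice:
        return slice(self.start_idx, self.end_idx + 1)


def segments(labeling: Labeling, times: np.ndarray) -> list[Segment]:
    """Contiguous runs of identical labels with their latencies."""
    labels = labeling.labels
    times = np.asarray(times, dtype=float)
    out: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append(Segment(int(labels[start]), start, i - 1,
                               float(times[start]), float(times[i - 1])))
            start = i
    return out


def _duration_ms(seg: Segment, step: float) -> float:
    # inclusive window: n samples cover n*step ms of signal
    return seg.n_samples * step


def merge_thin_maps(labeling: Labeling, data: np.ndarray, times: np.ndarray,
                    cfg: PipelineConfig) -> Labeling:
    """Absorb sub-threshold-duration cluster maps into a correlated neighbour.

    A segment shorter than ``thin_map_ms`` whose mean topography correlates
    above ``thin_map_corr`` with an adjacent segment's mean topography takes
    the better-correlated neighbour's label; repeated to a fixed point.
    Labels outside absorbed segments never change.
    """
    labels = labeling.labels.copy()
    times = np.asarray(times, dtype=float)
    step = times[1] - times[0]
    changed = True
    while changed:
        changed = False
        segs = segments(Labeling(labels, labeling.K), times)
        if len(segs) < 2:
            break
        for i, seg in enumerate(segs):
            if _duration_ms(seg, step) >= cfg.thin_map_ms:
                continue
            best_corr, best_label = -np.inf, None
            for j in (i - 1, i + 1):
                if not 0 <= j < len(segs):
                    continue
                try:
                    c = spatial_correlation(
                        mean_topography(data, seg.sl),
                        mean_topography(data, segs[j].sl),
                        centered=cfg.centered,
                    )
                except ZeroDivisionError:
                    continue
                if c > best_corr:
                    best_corr, best_label = c, segs[j].label
            if best_label is not None and best_corr > cfg.thin_map_corr:
                labels[seg.sl] = best_label
                changed = True
                break  # re-derive segments after each absorption
    return Labeling(labels, labeling.K)


def _relax_ladder(start: float, floor: float, step: float) -> list[float]:
    vals = [start]
    v = start
    while v - step >= floor - 1e-9:
        v = round(v - step, 10)
        vals.append(v)
    return vals


@dataclass
class _Candidate:
    seg: Segment
    isim: float
    topo: np.ndarray
    corr: float


def window_candidates(
    labeling: Labeling,
    data: np.ndarray,
    times: np.ndarray,
    cfg: PipelineConfig,
    template: TemplateMap | None = None,
    interval: tuple[float, float] | None = None,
) -> list[_Candidate]:
    """Candidate cluster maps: segments of ≥ 2 samples overlapping the search
    interval, with their inner similarity, mean topography, and template
    correlation.  Thin maps are absorbed first when ``cfg.merge_thin``."""
    times = np.asarray(times, dtype=float)
    if interval is None:
        if template is None:
            raise ValueError("need a template or an explicit search interval")
        interval = template.interval
    lo, hi = interval
    if cfg.merge_thin:
        labeling = merge_thin_maps(labeling, data, times, cfg)
    cands: list[_Candidate] = []
    for seg in segments(labeling, times):
        if seg.n_samples < 2 or seg.end_ms < lo or seg.start_ms > hi:
            continue
        try:
            isim = inner_similarity(data[seg.sl], centered=cfg.centered)
            topo = mean_topography(data, seg.sl)
            corr = (spatial_correlation(topo, template.topography,
                                        centered=cfg.centered)
                    if template is not None else np.nan)
        except ZeroDivisionError:
            continue
        cands.append(_Candidate(seg, isim, topo, corr))
    return cands


def pick_window(
    cands: list[_Candidate],
    cfg: PipelineConfig,
    with_template: bool,
    innersim_thr: float,
    corr_thr: float,
    relax: bool = True,
    data: np.ndarray | None = None,
    template: TemplateMap | None = None,
) -> TimeWindow | None:
    """Select the best candidate under the (possibly relaxing) thresholds.

    When ``data`` is given, the window is the union of the contiguous chain
    of qualifying cluster maps around the best candidate: adjacent segments
    that also correlate with the template above the accepted threshold are
    absorbed (a component often spans several consensus maps — rise, core,
    decay — all sharing its topography), and the window statistics are
    recomputed over the merged span.
    """
    if not cands:
        return None
    is_ladder = _relax_ladder(innersim_thr, cfg.innersim_floor, cfg.corr_step) \
        if relax else [innersim_thr]
    c_ladder = _relax_ladder(corr_thr, cfg.corr_tw_floor, cfg.corr_step) \
        if relax else [corr_thr]

    def build(c: _Candidate) -> TimeWindow:
        return TimeWindow(start_ms=c.seg.start_ms, end_ms=c.seg.end_ms,
                          start_idx=c.seg.start_idx, end_idx=c.seg.end_idx,
                          mean_topo=c.topo, innersim=c.isim, corr=c.corr)

    for is_thr in is_ladder:
        passing = [c for c in cands if c.isim >= is_thr]
        if not passing:
            continue
        if not with_template:
            # no spatial reference: best inner similarity wins
            passing.sort(key=lambda c: (-c.isim, -c.seg.n_samples,
                                        c.seg.start_idx))
            return build(passing[0])
        for c_thr in c_ladder:
            kept = [c for c in passing if c.corr >= c_thr]
            if kept:
                # correlations are compared at 0.01 resolution: among
                # near-ties (common when several sub-segments of one
                # component all correlate ~1.0) the longer, earlier map wins
                kept.sort(key=lambda c: (-np.floor(c.corr * 100.0),
                                         -c.seg.n_samples, c.seg.start_idx))
                if data is None:
                    return build(kept[0])
                return _chain_union(kept[0], cands, is_thr, c_thr, cfg, data,
                                    template)
    return None


def _chain_union(best: _Candidate, cands: list[_Candidate], is_thr: float,
                 c_thr: float, cfg: PipelineConfig, data: np.ndarray,
                 template: TemplateMap | None) -> TimeWindow:
    """Union of time-adjacent candidates around ``best`` that also qualify.

    A neighbour joins the chain when it matches the template at the accepted
    correlation threshold and its own maps are at least moderately coherent
    (inner similarity >= min(accepted threshold, 0.5)), which keeps
    transition slivers between components out of the window.
    """
    ordered = sorted(cands, key=lambda c: c.seg.start_idx)
    pos = ordered.index(best)
    isim_guard = min(is_thr, 0.5)

    def qualifies(c: _Candidate) -> bool:
        return c.corr >= c_thr and c.isim >= isim_guard

    lo_i, hi_i = pos, pos
    while lo_i > 0 and \
            ordered[lo_i - 1].seg.end_idx + 1 == ordered[lo_i].seg.start_idx \
            and qualifies(ordered[lo_i - 1]):
        lo_i -= 1
    while hi_i < len(ordered) - 1 and \
            ordered[hi_i].seg.end_idx + 1 == ordered[hi_i + 1].seg.start_idx \
            and qualifies(ordered[hi_i + 1]):
        hi_i += 1
    start, end = ordered[lo_i].seg, ordered[hi_i].seg
    sl = slice(start.start_idx, end.end_idx + 1)
    topo = mean_topography(data, sl)
    corr = best.corr
    if template is not None:
        try:
            corr = spatial_correlation(topo, template.topography,
                                       centered=cfg.centered)
        except ZeroDivisionError:
            pass
    return TimeWindow(start_ms=start.start_ms, end_ms=end.end_ms,
                      start_idx=start.start_idx, end_idx=end.end_idx,
                      mean_topo=topo,
                      innersim=inner_similarity(data[sl], centered=cfg.centered),
                      corr=corr)


def determine_time_window(
    labeling: Labeling,
    data: np.ndarray,
    times: np.ndarray,
    cfg: PipelineConfig,
    template: TemplateMap | None = None,
    interval: tuple[float, float] | None = None,
    innersim_thr: float | None = None,
    corr_thr: float | None = None,
    relax: bool = True,
) -> TimeWindow | None:
    """Determine the component's time window from a labeling, or ``None``.

    Candidate cluster maps are segments of at least two samples overlapping
    the search interval with inner similarity above the threshold; among
    those, segments correlating with the template above the correlation
    threshold compete, and the highest correlation wins (ties: longer
    duration, then earlier onset).  With ``relax=True`` the correlation
    threshold steps down by ``corr_step`` to its floor and, if still empty,
    the inner-similarity threshold relaxes the same way ("adjusted if no map
    is found").  ``None`` means not identified.
    """
    cands = window_candidates(labeling, data, times, cfg, template, interval)
    return pick_window(
        cands, cfg, with_template=template is not None,
        innersim_thr=cfg.innersim_tw_thr if innersim_thr is None else innersim_thr,
        corr_thr=cfg.corr_tw_thr if corr_thr is None else corr_thr,
        relax=relax, data=data, template=template)


def score_window(data: np.ndarray, window: TimeWindow, template: TemplateMap,
                 channels: list[str], centered: bool = False) -> ScoreRow:
    """Assemble the scoring record for one window on one dataset."""
    topo = mean_topography(data, window)
    return ScoreRow(
        tw_start=window.start_ms,
        tw_end=window.end_ms,
        innersim=inner_similarity(data[window.sl], centered=centered),
        amplitude=window_amplitude(data, window, template.site, channels),
        corr=spatial_correlation(topo, template.topography, centered=centered),
    )


def grand_average(epochsets: list[EpochSet]) -> np.ndarray:
    """Grand-average ERP over all subjects, conditions, and trials."""
    return np.mean([e.erp() for e in epochsets], axis=0)


# ---------------------------------------------------------------------------
# method screening and optimal K
# ---------------------------------------------------------------------------


def _screen_method(concat: np.ndarray, blocks: list[slice], method: str,
                   times: np.ndarray, template: TemplateMap,
                   cfg: PipelineConfig, master_seed: int, context: tuple) -> bool:
    """Does one base method recover a coherent window in every condition block?"""
    step = np.asarray(times, float)[1] - np.asarray(times, float)[0]
    repeats = cfg.mn_repeats if method in STOCHASTIC_METHODS else 1
    passes = 0
    for rep in range(repeats):
        seed = derive_seed(master_seed, *context, method, rep)
        try:
            lab = cluster_epoch(concat, cfg.K, method, seed=seed,
                                normalize=cfg.normalize_maps)
        except ClusteringError:
            continue
        ok = True
        for b in blocks:
            sub = Labeling(lab.labels[b], lab.K)
            win = determine_time_window(
                sub, concat[b], times, cfg, template=template,
                innersim_thr=cfg.mn_innersim_thr, relax=False)
            if win is None or win.n_samples * step <= cfg.mn_duration_ms:
                ok = False
                break
        passes += ok
    return passes * 2 > repeats


def mn_select_methods(
    condition_erps: list[np.ndarray],
    times: np.ndarray,
    template: TemplateMap,
    cfg: PipelineConfig,
    candidates: tuple[str, ...] = METHOD_NAMES,
    master_seed: int = 0,
    replacement: list[str] | None = None,
    context: tuple = (),
) -> tuple[list[str], bool]:
    """Screen candidate clustering methods on one subject's concatenated ERP.

    ``condition_erps`` are the subject's per-condition ERPs; they are stacked
    along time and each condition block must yield a qualifying window.
    Returns ``(methods, used_replacement)``: when zero or one method survives,
    the replacement list (methods screened at the group level) is returned
    instead.
    """
    if not candidates:
        raise ValueError("no candidate methods")
    n = condition_erps[0].shape[0]
    concat = np.vstack(condition_erps)
    blocks = [slice(i * n, (i + 1) * n) for i in range(len(condition_erps))]
    selected = [m for m in candidates
                if _screen_method(concat, blocks, m, times, template, cfg,
                                  master_seed, context)]
    if len(selected) <= 1:
        fallback = replacement if replacement else list(candidates)
        return list(fallback), True
    return selected, False


def estimate_optimal_k(
    group_erp: np.ndarray,
    times: np.ndarray,
    cfg: PipelineConfig,
    templates: list[TemplateMap],
    methods: list[str] | tuple[str, ...] = METHOD_NAMES,
    master_seed: int = 0,
    stable_delta: float = 0.02,
    innersim_target: float = 0.95,
) -> tuple[int, dict[int, float]]:
    """Scan K over ``cfg.k_range`` on the group-average ERP.

    For each K the group ERP is consensus-clustered and every target
    component's window is determined against its template; the profile value
    is the worst target's inner similarity (0 when a target is not
    identified).  Returns the smallest K whose profile is ≥
    ``innersim_target`` and changes by ≤ ``stable_delta`` at K+1; if no K
    qualifies, the argmax with a warning.  The profile is returned alongside
    for inspection.
    """
    klo, khi = cfg.k_range
    if khi > group_erp.shape[0] // 4:
        raise ValueError("k_range upper bound too large for this epoch length")
    profile: dict[int, float] = {}
    for K in range(klo, khi + 1):
        lab = consensus_within_trial(group_erp, list(methods), K,
                                     master_seed=master_seed,
                                     context=("optimal_k", K),
                                     normalize=cfg.normalize_maps)
        vals = []
        for tpl in templates:
            win = determine_time_window(lab, group_erp, times,
                                        cfg.with_(K=K), template=tpl)
            vals.append(0.0 if win is None else win.innersim)
        profile[K] = min(vals)
    ks = sorted(profile)
    for K in ks[:-1]:
        if profile[K] >= innersim_target and \
                abs(profile[K + 1] - profile[K]) <= stable_delta:
            return K, profile
    best = max(ks, key=lambda k: profile[k])
    logger.warning("no K stabilised above %.2f; falling back to argmax K=%d",
                   innersim_target, best)
    return best, profile


def derive_template(
    group_erp: np.ndarray,
    times: np.ndarray,
    cfg: PipelineConfig,
    interval: tuple[float, float],
    site: str,
    name: str = "component",
    methods: list[str] | tuple[str, ...] = METHOD_NAMES,
    master_seed: int = 0,
) -> TemplateMap:
    """Template map from group-average data: consensus-cluster, pick the
    highest-inner-similarity window in the interval, use its mean topography."""
    lab = consensus_within_trial(group_erp, list(methods), cfg.K,
                                 master_seed=master_seed,
                                 context=("template", name),
                                 normalize=cfg.normalize_maps)
    win = determine_time_window(lab, group_erp, times, cfg, template=None,
                                interval=interval)
    if win is None:
        raise RuntimeError(
            f"no qualifying window in {interval} on the group ERP; "
            "relax innersim_tw_thr / innersim_floor")
    return TemplateMap(name=name, topography=win.mean_topo, interval=interval,
                       site=site)


# ---------------------------------------------------------------------------
# trial selection and the full study run
# ---------------------------------------------------------------------------


@dataclass
class TrialSelection:
    selected_ids: list[int]
    labelings: dict[int, Labeling]       # all usable trials
    windows: dict[int, TimeWindow]       # windows of the selected trials
    corr_thr: float
    innersim_thr: float
    floor_hit: bool


def cluster_trials(
    epochset: EpochSet,
    methods: list[str],
    cfg: PipelineConfig,
    master_seed: int = 0,
) -> dict[int, Labeling]:
    """Within-trial consensus labeling for every usable trial (template-free,
    so one pass serves the selection of every target component)."""
    labelings: dict[int, Labeling] = {}
    for i, trial in enumerate(epochset.trials):
        ctx = (epochset.subject_id, epochset.condition, i)
        try:
            labelings[i] = consensus_within_trial(trial, methods, cfg.K,
                                                  master_seed=master_seed,
                                                  context=ctx,
                                                  normalize=cfg.normalize_maps)
        except ClusteringError:
            logger.warning("%s/%s trial %d: all methods failed",
                           epochset.subject_id, epochset.condition, i)
    return labelings


def select_trials(
    epochset: EpochSet,
    template: TemplateMap,
    methods: list[str],
    cfg: PipelineConfig,
    master_seed: int = 0,
    labelings: dict[int, Labeling] | None = None,
) -> TrialSelection:
    """Consensus-cluster every trial and keep those exhibiting the component.

    A trial is retained when a window matching the template can be determined
    at the trial thresholds.  The correlation threshold decrements from
    ``corr_trial_start`` to ``corr_trial_floor`` until at least
    ``retain_frac`` of trials are kept; if the floor still retains fewer, the
    inner-similarity threshold relaxes stepwise as well, and whatever is
    retained at the final rung is returned with ``floor_hit=True``.
    """
    if epochset.n_trials == 0:
        raise ValueError("epoch set has no trials")
    if labelings is None:
        labelings = cluster_trials(epochset, methods, cfg, master_seed)
    target = cfg.retain_frac * epochset.n_trials

    # relaxation schedule: first the corr threshold, then inner similarity
    rungs = [(cfg.innersim_trial_thr, c)
             for c in _relax_ladder(cfg.corr_trial_start, cfg.corr_trial_floor,
                                    cfg.corr_step)]
    rungs += [(i, cfg.corr_trial_floor)
              for i in _relax_ladder(cfg.innersim_trial_thr, cfg.innersim_floor,
                                     cfg.corr_step)[1:]]

    cands = {i: window_candidates(lab, epochset.trials[i], epochset.times,
                                  cfg, template=template)
             for i, lab in labelings.items()}
    windows: dict[int, TimeWindow] = {}
    is_thr = c_thr = None
    for is_thr, c_thr in rungs:
        windows = {}
        for i in cands:
            win = pick_window(cands[i], cfg, with_template=True,
                              innersim_thr=is_thr, corr_thr=c_thr, relax=False,
                              data=epochset.trials[i], template=template)
            if win is not None:
                windows[i] = win
        if len(windows) >= target:
            return TrialSelection(sorted(windows), labelings, windows,
                                  c_thr, is_thr, False)
    logger.warning("%s/%s: retention floor hit (%d/%d trials kept)",
                   epochset.subject_id, epochset.condition, len(windows),
                   epochset.n_trials)
    return TrialSelection(sorted(windows), labelings, windows,
                          c_thr, is_thr, True)


@dataclass
class SubjectResult:
    """Per subject/condition outcome for one target component."""

    subject_id: str
    condition: str
    component: str
    methods: list[str]
    used_replacement: bool
    selection: TrialSelection
    subject_labeling: Labeling | None = None
    window: TimeWindow | None = None
    score: ScoreRow | None = None
    trial_scores: dict[int, ScoreRow] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def identified(self) -> bool:
        return self.window is not None


def _score_table(results: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        base = dict(Subj_ID=r.subject_id, condition=r.condition,
                    component=r.component, n_selected=len(r.selection.selected_ids),
                    methods=",".join(r.methods))
        if r.score is not None:
            base.update(r.score.as_dict())
        else:
            base.update({k: np.nan for k in
                         ("TW_start_ms", "TW_end_ms", "Innsim", "Amp_uV", "Corr")})
        rows.append(base)
    return pd.DataFrame(rows)


def run_study(
    epochsets: list[EpochSet],
    templates: dict[str, TemplateMap],
    cfg: PipelineConfig,
    candidates: tuple[str, ...] = METHOD_NAMES,
    master_seed: int | None = None,
    selection_template: str | None = None,
) -> tuple[list[SubjectResult], pd.DataFrame]:
    """Run the full pipeline for every subject/condition and target component.

    Method screening is performed once per subject on its concatenated
    condition ERPs against ``selection_template`` (default: the template whose
    component has the widest search interval, normally the dominant one); the
    replacement list is screened the same way on the group-average ERP.
    Returns the subject results and a long-format score table.
    """
    if master_seed is None:
        master_seed = cfg.seed
    if not templates:
        raise ValueError("need at least one template")
    sel_name = selection_template or max(
        templates, key=lambda k: templates[k].interval[1] - templates[k].interval[0])
    sel_tpl = templates[sel_name]
    times = epochsets[0].times
    channels = epochsets[0].channels
    for e in epochsets:
        if e.channels != channels or not np.array_equal(e.times, times):
            raise ValueError("all epoch sets must share channels and times")

    by_subject: dict[str, dict[str, EpochSet]] = {}
    for e in epochsets:
        by_subject.setdefault(e.subject_id, {})[e.condition] = e
    conditions = sorted({e.condition for e in epochsets})

    # replacement list from the group level
    group_cond_erps = [
        np.mean([by_subject[s][c].erp() for s in by_subject if c in by_subject[s]],
                axis=0)
        for c in conditions
    ]
    replacement, _ = mn_select_methods(group_cond_erps, times, sel_tpl, cfg,
                                       candidates, master_seed,
                                       replacement=list(candidates),
                                       context=("group",))

    results: list[SubjectResult] = []
    for subj, conds in by_subject.items():
        erps = [conds[c].erp() for c in conditions if c in conds]
        methods, used_repl = mn_select_methods(
            erps, times, sel_tpl, cfg, candidates, master_seed,
            replacement=replacement, context=("subject", subj))
        for cond in conditions:
            if cond not in conds:
                continue
            eset = conds[cond]
            labelings = cluster_trials(eset, methods, cfg, master_seed)
            for comp, tpl in templates.items():
                res = _run_one(eset, tpl, comp, methods, used_repl, cfg,
                               master_seed, channels, labelings)
                results.append(res)
    return results, _score_table(results)


def _run_one(eset: EpochSet, tpl: TemplateMap, comp: str, methods: list[str],
             used_repl: bool, cfg: PipelineConfig, master_seed: int,
             channels: list[str],
             labelings: dict[int, Labeling] | None = None) -> SubjectResult:
    sel = select_trials(eset, tpl, methods, cfg, master_seed,
                        labelings=labelings)
    res = SubjectResult(eset.subject_id, eset.condition, comp, methods,
                        used_repl, sel)
    if sel.floor_hit:
        res.flags.append("retention_floor")
    if not sel.selected_ids:
        res.flags.append("no_trials_retained")
        return res
    labs = [sel.labelings[i] for i in sel.selected_ids]
    res.subject_labeling = consensus_across_trials(labs, cfg.K)
    # window and scores are read off the subject's full condition ERP; the
    # selected trials determine the consensus labeling, but every trial
    # carries signal, so the full average is the better-resolved estimate
    erp = eset.erp()
    res.window = determine_time_window(res.subject_labeling, erp, eset.times,
                                       cfg, template=tpl)
    if res.window is None:
        res.flags.append("not_identified")
        return res
    res.score = score_window(erp, res.window, tpl, channels, cfg.centered)
    for i in sel.selected_ids:
        try:
            res.trial_scores[i] = score_window(eset.trials[i], sel.windows[i],
                                               tpl, channels, cfg.centered)
        except ZeroDivisionError:
            continue
    return res
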