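"""End-to-end orchestration: per-cell records, group comparisons, LDA.

``assemble_cell_record`` runs one neuron through the full chain —
stationarity segmentation, ISI statistics, burst/pause detection, GLO
fit and pattern label, waveform metrics — and emits one row of the
cohort feature table.  ``compare_groups`` applies Mann-Whitney tests to
continuous variables and chi-squared tests to contingencies (SFB > 5%
yes/no, firing-pattern labels).  ``run_pipeline`` ties everything to
files: a manifest of cells in, a results bundle (cells.csv,
group_stats.csv, lda_results.json, resolved config) out, deterministic
under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .burst import BurstCriteria, PauseCriteria, burst_stats, detect_bursts, \
    detect_pauses
from .discriminant import LDA_VARIABLES, BestSubsetLDA
from .glo import GLOFitConfig, classify_pattern, fit_glo
from .labelling import FGCriteria
from .spiketrain import SpikeTrain, autocorrelogram, isi_stats, \
    load_spike_times
from .stationarity import DEFAULT_WINDOWS, multiple_filter_test
from .waveform import DAIdentificationCriteria, Waveform, ap_metrics, \
    average_waveform, is_putative_da, load_waveform

__all__ = [
    "PipelineConfig",
    "assemble_cell_record",
    "compare_groups",
    "run_pipeline",
]

log = logging.getLogger("dastride")


@dataclass(frozen=True)
class StationarityConfig:
    windows: tuple = DEFAULT_WINDOWS
    alpha: float = 0.05
    n_null_sims: int = 1000
    grid_step: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    """All module criteria and thresholds plus the master seed.

    Serialises losslessly to a JSON-compatible dict; every run writes the
    resolved configuration next to its results.
    """

    burst: BurstCriteria = BurstCriteria()
    pause: PauseCriteria = PauseCriteria()
    glo: GLOFitConfig = GLOFitConfig()
    fg: FGCriteria = FGCriteria()
    stationarity: StationarityConfig = StationarityConfig()
    da_criteria: DAIdentificationCriteria = DAIdentificationCriteria()
    use_stationary_segment: bool = True
    excess_kurtosis: bool = False
    onset_sd_mult: float = 3.0
    lda_n_splits: int = 1000
    lda_n_perm: int = 200
    lda_n_splits_perm: int = 200
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in (("burst", BurstCriteria), ("pause", PauseCriteria),
                         ("glo", GLOFitConfig), ("fg", FGCriteria),
                         ("stationarity", StationarityConfig),
                         ("da_criteria", DAIdentificationCriteria)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()}
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)


def _cell_seed(master_seed: int, cell_id: str) -> int:
    return (int(master_seed) * 1000003 + zlib.crc32(cell_id.encode())) \
        % (2 ** 31)


def assemble_cell_record(train: SpikeTrain, waveform, metadata: dict | None,
                         config: PipelineConfig = PipelineConfig(),
                         stationarity_threshold: float | None = None) -> dict:
    """One neuron -> one row of the 13-variable cohort table.

    ``waveform`` is a list of sweeps (averaged here), a single averaged
    :class:`Waveform`, or None.  Stage failures are recorded as NaN
    fields plus an entry in the ``flags`` column rather than aborting the
    record.
    """
    rec: dict = dict(metadata or {})
    rec.setdefault("cell_id", train.cell_id)
    flags: list[str] = []
    seed = _cell_seed(config.master_seed, str(rec["cell_id"]))
    for v in LDA_VARIABLES:
        rec[v] = np.nan
    rec.update(intraburst_hz=np.nan, pause_dur_s=np.nan, glo_pattern="",
               is_bursty=np.nan, is_putative_da=np.nan,
               seg_start_s=0.0, seg_end_s=train.duration,
               n_spikes=train.n_spikes)

    seg = train
    try:
        st = multiple_filter_test(
            train, windows=config.stationarity.windows,
            alpha=config.stationarity.alpha,
            n_null_sims=config.stationarity.n_null_sims,
            grid_step=config.stationarity.grid_step,
            seed=seed, threshold=stationarity_threshold)
        if config.use_stationary_segment and st.tested:
            seg = train.crop(*st.longest_segment)
            rec["seg_start_s"], rec["seg_end_s"] = st.longest_segment
    except Exception as exc:  # pragma: no cover - defensive
        flags.append(f"stationarity:{exc}")

    try:
        stats = isi_stats(seg, excess_kurtosis=config.excess_kurtosis)
        rec.update(mean_rate_hz=stats.mean_rate, cv_pct=stats.cv,
                   isi_skewness=stats.skewness, isi_kurtosis=stats.kurtosis)
        if np.isnan(stats.cv):
            flags.append("isi:undefined")
    except Exception as exc:
        flags.append(f"isi:{exc}")

    try:
        bursts = detect_bursts(seg, config.burst)
        bs = burst_stats(seg, bursts, config.burst)
        ps = detect_pauses(seg, bursts, config.pause)
        rec.update(sfb_pct=bs.sfb, bursts_per_min=bs.bursts_per_min,
                   intraburst_hz=bs.mean_intraburst_rate,
                   is_bursty=bs.is_bursty,
                   pauses_per_min=ps.pauses_per_min,
                   pause_dur_s=ps.mean_pause_duration)
    except Exception as exc:
        flags.append(f"burst:{exc}")

    try:
        fit = fit_glo(seg, config.glo)
        ach = autocorrelogram(seg, config.glo.bin_width, config.glo.max_lag)
        pattern = classify_pattern(fit, ach, config.glo)
        rec.update(glo_mu_s=fit.params.mu, glo_s_s=fit.params.s,
                   glo_beta=fit.params.beta, glo_log_sigma2=fit.log_sigma2,
                   glo_pattern=pattern.label)
        if not fit.converged:
            flags.append("glo:unconverged")
    except Exception as exc:
        flags.append(f"glo:{exc}")

    try:
        if waveform is not None:
            wf = waveform if isinstance(waveform, Waveform) \
                else average_waveform(list(waveform))
            m = ap_metrics(wf, onset_sd_mult=config.onset_sd_mult)
            rec.update(ap_dur_ms=m.duration_ms, rel_trough=m.relative_trough)
            if not np.isnan(rec["mean_rate_hz"]):
                rec["is_putative_da"] = is_putative_da(
                    m, rec["mean_rate_hz"], config.da_criteria)
        else:
            flags.append("waveform:missing")
    except Exception as exc:
        flags.append(f"waveform:{exc}")

    rec["flags"] = ";".join(flags)
    return rec


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    adj = np.empty_like(pvals)
    running = 0.0
    m = len(pvals)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_groups(records: pd.DataFrame, group_col: str = "group",
                   variables=None, categorical=("is_bursty", "glo_pattern"),
                   alpha: float = 0.05, holm: bool = False) -> pd.DataFrame:
    """Two-group report: Mann-Whitney for continuous, chi-squared for counts.

    Continuous variables get two-sided Mann-Whitney U with means +/- SEM
    and medians per group; categorical ones (e.g. the SFB > 5%
    contingency and the GLO pattern label) get a Pearson chi-squared test
    on the group x category table.  Uncorrected p-values are reported
    (with an optional Holm column, off by default).
    """
    groups = records[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    ga, gb = sorted(map(str, groups))
    a = records[records[group_col].astype(str) == ga]
    b = records[records[group_col].astype(str) == gb]
    if variables is None:
        variables = [v for v in LDA_VARIABLES if v in records.columns]
    rows = []
    for v in variables:
        xa = a[v].dropna().to_numpy(dtype=float)
        xb = b[v].dropna().to_numpy(dtype=float)
        if len(xa) < 3 or len(xb) < 3:
            raise ValueError(f"{v}: need n >= 3 per group for the rank test")
        u, p = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({
            "variable": v, "test": "mann-whitney",
            "n_" + ga: len(xa), "n_" + gb: len(xb),
            "mean_" + ga: xa.mean(),
            "sem_" + ga: xa.std(ddof=1) / np.sqrt(len(xa)),
            "mean_" + gb: xb.mean(),
            "sem_" + gb: xb.std(ddof=1) / np.sqrt(len(xb)),
            "median_" + ga: float(np.median(xa)),
            "median_" + gb: float(np.median(xb)),
            "statistic": u, "p_value": p,
        })
    for v in categorical or ():
        if v not in records.columns:
            continue
        tab = pd.crosstab(records[group_col], records[v])
        if tab.shape[1] < 2:
            continue  # degenerate: a single category observed
        chi2, p, dof, _ = scipy.stats.chi2_contingency(tab.to_numpy(),
                                                       correction=False)
        rows.append({"variable": v, "test": "chi-squared",
                     "n_" + ga: int(tab.loc[ga].sum()),
                     "n_" + gb: int(tab.loc[gb].sum()),
                     "statistic": chi2, "p_value": p})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < alpha
    if holm:
        out["p_holm"] = _holm(out["p_value"].to_numpy())
    return out


def run_pipeline(config: PipelineConfig, manifest, out_dir) -> dict:
    """Analyse a cohort listed in a manifest; write the results bundle.

    ``manifest`` is a CSV path or DataFrame with columns ``cell_id,
    spike_path, waveform_path, group`` (plus optional anatomy columns
    carried through).  Outputs: cells.csv, group_stats.csv (two-group
    cohorts), lda_results.json (two-group cohorts with enough complete
    cells), config.json.  Per-cell failures are isolated and flagged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest: list cells as cell_id, spike_path, "
                         "waveform_path, group")
    rows = []
    for _, m in manifest.iterrows():
        meta = {k: m[k] for k in manifest.columns
                if k not in ("spike_path", "waveform_path")}
        try:
            train = load_spike_times(m["spike_path"],
                                     cell_id=str(m["cell_id"]))
            wf = load_waveform(m["waveform_path"]) \
                if isinstance(m.get("waveform_path"), str) else None
            rows.append(assemble_cell_record(train, wf, meta, config))
        except Exception as exc:
            log.error("cell %s failed: %s", m.get("cell_id"), exc)
            rows.append({**meta, "flags": f"load:{exc}"})
    records = pd.DataFrame(rows)
    records.to_csv(out / "cells.csv", index=False)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2,
                                                default=str))
    bundle = {"records": records, "out_dir": str(out)}

    groups = records.get("group")
    if groups is not None and records["group"].nunique() == 2:
        try:
            stats = compare_groups(records)
            stats.to_csv(out / "group_stats.csv", index=False)
            bundle["group_stats"] = stats
        except Exception as exc:
            log.warning("group comparison skipped: %s", exc)
        complete = records.dropna(subset=list(LDA_VARIABLES))
        n_dropped = len(records) - len(complete)
        if n_dropped:
            log.warning("%d cell(s) with missing variables excluded from "
                        "LDA", n_dropped)
        if complete.groupby("group").size().min() >= 4:
            est = BestSubsetLDA(candidates=list(LDA_VARIABLES),
                                n_splits=config.lda_n_splits,
                                n_perm=config.lda_n_perm,
                                n_splits_perm=config.lda_n_splits_perm,
                                random_state=config.master_seed)
            est.fit(complete[list(LDA_VARIABLES)], complete["group"])
            res = est.result_
            lda_out = {
                "best_subset": list(res.subset),
                "predictive_power_pct": res.predictive_power,
                "permutation_p": res.permutation_p,
                "full_data_accuracy_pct": res.full_data_accuracy,
                "n_splits": res.n_splits, "n_perm": res.n_perm,
                "scaled_down": res.scaled_down, "mc_error": res.mc_error,
                "n_cells_excluded": n_dropped,
                "per_cell_calls": [
                    {"cell_id": str(c), "true": str(t), "predicted": str(p)}
                    for c, t, p in zip(complete["cell_id"], complete["group"],
                                       est.predict(complete[list(LDA_VARIABLES)]))],
            }
            (out / "lda_results.json").write_text(
                json.dumps(lda_out, indent=2))
            bundle["lda"] = lda_out
    return bundle
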