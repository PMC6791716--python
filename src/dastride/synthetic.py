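"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:
dopamine-like spike trains at 1-8 Hz drawn from the GLO generative model
(pacemaker, irregular, bursty-irregular and bursty-oscillatory regimes),
biphasic extracellular AP waveforms broader than 1.2 ms, two-group
13-variable feature tables with controlled separation, punctate ROI
intensity fields over noisy backgrounds, and multinomial region x
projection count tables.  Every generator is a pure function of its
specification and seed; ground truth is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .discriminant import LDA_VARIABLES
from .glo import GLOParams, simulate_glo
from .labelling import ROIMeasurement
from .waveform import Waveform

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "COHORT_PRESETS",
    "generate_cohort",
    "generate_feature_table",
    "generate_waveform_sweeps",
    "generate_roi_field",
    "generate_count_table",
]


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative settings for one cohort arm."""

    n_cells: int
    glo: GLOParams  # group-mean oscillator parameters
    burst_size_law: str = "poisson"  # "fixed" emulates single-spike cells
    glo_jitter_frac: float = 0.10  # lognormal SD fraction on mu and beta
    glo_jitter_frac_noise: float = 0.20  # on s and sigma2
    # biphasic waveform template (milliseconds / mV)
    wf_peak_ms: float = 2.0
    wf_trough_ms: float = 3.4
    wf_trough_ratio: float = 0.62
    wf_noise_sd_mv: float = 0.03
    wf_amplitude_mv: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("each group needs at least 2 cells")


@dataclass(frozen=True)
class CohortSpec:
    groups: dict  # name -> GroupSpec
    duration_s: float = 600.0
    n_sweeps: int = 20
    sample_rate_hz: float = 20e3
    seed: int | None = None


#: presets named after the study's group comparisons; effect directions
#: follow the reported group differences (high burstiness in the lateral
#: DLS-projecting arm, bursty lNAcc-projecting cells in the mSN, lower
#: rate and longer pauses in the mNAcc-projecting arm).  Effect sizes are
#: free parameters of the generator, not claims of fidelity.
COHORT_PRESETS = {
    "dls_lsn_vs_msn": CohortSpec(groups={
        "DLS-lSN": GroupSpec(15, GLOParams(mu=0.40, s=0.08, beta=2.5,
                                           sigma2=0.020),
                             wf_trough_ratio=0.68),
        "DLS-mSN": GroupSpec(9, GLOParams(mu=0.28, s=0.07, beta=1.0,
                                          sigma2=0.022),
                             burst_size_law="fixed", wf_trough_ratio=0.55),
    }),
    "msn_ds_vs_lnacc": CohortSpec(groups={
        "DS-mSN": GroupSpec(18, GLOParams(mu=0.30, s=0.05, beta=1.0,
                                          sigma2=0.020),
                            burst_size_law="fixed"),
        "lNAcc-mSN": GroupSpec(14, GLOParams(mu=0.45, s=0.10, beta=2.2,
                                             sigma2=0.015),
                               wf_trough_ratio=0.55),
    }),
    "lnacc_vs_mnacc": CohortSpec(groups={
        "lNAcc": GroupSpec(14, GLOParams(mu=0.24, s=0.05, beta=1.0,
                                         sigma2=0.018),
                           burst_size_law="fixed"),
        "mNAcc": GroupSpec(13, GLOParams(mu=0.55, s=0.14, beta=1.0,
                                         sigma2=0.020),
                           burst_size_law="fixed"),
    }),
}


def _jitter_params(g: GroupSpec, rng) -> GLOParams:
    def ln(mean, frac):
        return float(mean * rng.lognormal(0.0, frac)) if mean > 0 else 0.0
    return GLOParams(
        mu=ln(g.glo.mu, g.glo_jitter_frac),
        s=ln(g.glo.s, g.glo_jitter_frac_noise),
        beta=ln(g.glo.beta, g.glo_jitter_frac),
        sigma2=ln(g.glo.sigma2, g.glo_jitter_frac_noise),
    )


def generate_waveform_sweeps(group: GroupSpec, n_sweeps: int,
                             sample_rate_hz: float, rng) -> list[Waveform]:
    """Noisy biphasic sweeps around the group's waveform template."""
    dt = 1.0 / sample_rate_hz
    t_ms = np.arange(0.0, 8.0, dt * 1e3)
    wp, wt = 0.25, 0.65  # ms, Gaussian widths of the two components
    template = (group.wf_amplitude_mv
                * (np.exp(-0.5 * ((t_ms - group.wf_peak_ms) / wp) ** 2)
                   - group.wf_trough_ratio
                   * np.exp(-0.5 * ((t_ms - group.wf_trough_ms) / wt) ** 2)))
    sweeps = []
    for _ in range(n_sweeps):
        noise = rng.normal(0.0, group.wf_noise_sd_mv, size=template.size)
        sweeps.append(Waveform(template + noise, dt,
                               baseline_window=(0, int(1.0e-3 / dt))))
    return sweeps


@dataclass
class Cohort:
    """Generated cohort: raw materials, assembled records and truth."""

    trains: dict  # cell_id -> SpikeTrain
    sweeps: dict  # cell_id -> list[Waveform]
    records: pd.DataFrame | None  # assembled 13-variable table
    truth: dict  # manifest with seeds and per-cell ground truth


def generate_cohort(spec: CohortSpec, assemble: bool = True,
                    config=None) -> Cohort:
    """Generate GLO spike trains, waveforms and (optionally) the record table.

    Per cell the group-mean GLO parameters are jittered (lognormal), a
    600 s train is simulated, and noisy biphasic waveform sweeps are
    drawn.  With ``assemble=True`` the full pipeline builds each cell's
    13-variable record.  The truth manifest stores the seed, the spec and
    the per-cell generative parameters.
    """
    rng = np.random.default_rng(spec.seed)
    trains, sweeps, truth_cells = {}, {}, {}
    meta = []
    for gname, group in spec.groups.items():
        for i in range(group.n_cells):
            cid = f"{gname}_{i:02d}"
            p = _jitter_params(group, rng)
            trains[cid] = replace(
                simulate_glo(p, spec.duration_s,
                             seed=rng.integers(2 ** 31),
                             burst_size_law=group.burst_size_law),
                cell_id=cid)
            sweeps[cid] = generate_waveform_sweeps(
                group, spec.n_sweeps, spec.sample_rate_hz, rng)
            truth_cells[cid] = {"group": gname, **asdict(p)}
            meta.append({"cell_id": cid, "group": gname})
    records = None
    if assemble:
        from .pipeline import PipelineConfig, assemble_cell_record
        config = config or PipelineConfig()
        rows = []
        for m in meta:
            cid = m["cell_id"]
            rows.append(assemble_cell_record(trains[cid], sweeps[cid],
                                             metadata=m, config=config))
        records = pd.DataFrame(rows)
    truth = {"seed": spec.seed, "duration_s": spec.duration_s,
             "groups": {g: asdict(s) for g, s in spec.groups.items()},
             "cells": truth_cells}
    return Cohort(trains, sweeps, records, truth)


def generate_feature_table(n_per_group, effects=None, seed=None,
                           group_names=("A", "B"),
                           variables=LDA_VARIABLES) -> pd.DataFrame:
    """Two-group Gaussian feature table with controlled separation.

    ``effects`` maps variable names to the group-mean difference in
    pooled-SD units (unlisted variables are pure noise); ``n_per_group``
    is an int or a (nA, nB) pair.  Used to calibrate the LDA machinery
    where the ground truth must be exact.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_group, int):
        n_per_group = (n_per_group, n_per_group)
    effects = dict(effects or {})
    unknown = set(effects) - set(variables)
    if unknown:
        raise ValueError(f"unknown effect variables: {sorted(unknown)}")
    frames = []
    for gi, (gname, n) in enumerate(zip(group_names, n_per_group)):
        X = rng.normal(size=(n, len(variables)))
        for var, d in effects.items():
            X[:, list(variables).index(var)] += gi * d
        df = pd.DataFrame(X, columns=list(variables))
        df.insert(0, "cell_id", [f"{gname}_{i:02d}" for i in range(n)])
        df.insert(1, "group", gname)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_roi_field(bg_mean: float, bg_sd: float, n_puncta: int,
                       amplitude: float, size=(64, 64), seed=None,
                       puncta_sigma: float = 1.5,
                       min_separation: float = 8.0) -> ROIMeasurement:
    """Gaussian background plus disjoint Gaussian puncta; truth = n_puncta.

    Puncta centres keep ``min_separation`` pixels apart (and clear of the
    border); raises if they cannot be placed after many tries.
    """
    if min(size) < 32:
        raise ValueError("field must be at least 32 x 32")
    rng = np.random.default_rng(seed)
    field_arr = rng.normal(bg_mean, bg_sd, size=size)
    margin = 4 * puncta_sigma
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_puncta:
        c = (rng.uniform(margin, size[0] - margin),
             rng.uniform(margin, size[1] - margin))
        if all(np.hypot(c[0] - a, c[1] - b) >= min_separation
               for a, b in centres):
            centres.append(c)
        tries += 1
        if tries > 1000 * max(n_puncta, 1):
            raise ValueError("cannot place puncta disjointly")
    yy, xx = np.mgrid[0:size[0], 0:size[1]]
    for cy, cx in centres:
        field_arr += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * puncta_sigma ** 2))
    return ROIMeasurement(background_mean=bg_mean, background_sd=bg_sd,
                          roi_pixels=field_arr,
                          mask=np.ones(size, dtype=bool))


def generate_count_table(region_profile: pd.DataFrame, totals,
                         seed=None, deterministic: bool = False
                         ) -> pd.DataFrame:
    """Multinomial counts per region from probability profiles.

    ``region_profile`` rows are probability vectors over projections;
    ``totals`` gives each region's cell count (scalar or per-region).
    ``deterministic`` returns the rounded expected counts instead of a
    draw.
    """
    probs = region_profile.to_numpy(dtype=float)
    if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
        raise ValueError("profile rows must be probability vectors")
    if np.isscalar(totals):
        totals = pd.Series(totals, index=region_profile.index)
    rng = np.random.default_rng(seed)
    rows = []
    for r, pvec in zip(region_profile.index, probs):
        n = int(totals[r])
        if deterministic:
            rows.append(np.round(n * pvec).astype(int))
        else:
            rows.append(rng.multinomial(n, pvec))
    return pd.DataFrame(rows, index=region_profile.index,
                        columns=region_profile.columns)
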