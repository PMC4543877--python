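"""Config-driven experiment suite.

Reproduces the simulation experiments end to end: intact vs. hair-field-
ablated runs for the three pattern variants (Mc / Mm / Mmsd), the SP-lead
phase sweep, and the triangular / augmented-triangular phase-sensitivity
tests.  Each run emits joint-angle traces, the SP-vs-HS correlogram and a
machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, synthetic_data
from .pattern_formation import (
    FourierPattern,
    make_augmented_triangular,
    make_triangular,
    sample_variant,
    sine_pattern,
)
from .rhythm_core import (
    OSCILLATOR_NAMES,
    CouplingEdge,
    NetworkSpec,
    coupling_pair,
    default_network,
    network_from_dict,
)
from .skeleton import KinematicChain, ServoConfig, TrialResult, simulate_trial

__all__ = [
    "ExperimentConfig",
    "CONDITIONS",
    "VARIANTS",
    "DEFAULT_PHASE_LEADS",
    "resolve_patterns",
    "ablation_changes_only_amplitude_and_offset",
    "run_condition",
    "run_phase_sweep",
    "load_config",
]

log = logging.getLogger("antcpg")

CONDITIONS = ("intact", "ablated")
VARIANTS = ("Mc", "Mm", "Mmsd", "triangular", "augmented")
#: SP phase leads (degrees) swept in the phase experiment
DEFAULT_PHASE_LEADS = (-40, -20, 0, 10, 20, 40, 60, 90, 180)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: a study condition, a pattern variant, and run
    settings.  ``phase_leads`` applies only to the phase sweep."""

    condition: str = "intact"
    variant: str = "Mc"
    duration: float = 60.0
    transient: float = 5.0
    seed: int = 1
    phase_leads: tuple = DEFAULT_PHASE_LEADS
    outdir: str | None = None
    network: NetworkSpec | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.duration <= 0 or self.transient < 0:
            raise ValueError("invalid duration/transient")

    def resolve_network(self) -> NetworkSpec:
        if self.network is not None:
            return self.network
        return default_network(self.condition)


def resolve_patterns(
    variant: str, rng: np.random.Generator | None = None
) -> dict[str, FourierPattern]:
    """Patterns per oscillator for a variant; the neck is always a plain
    sinusoid.  Mmsd draws a fresh magnitude perturbation per call."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("Mc", "Mm", "Mmsd"):
        variants = synthetic_data.default_variants()
        hs = sample_variant(variants["hs"][variant], rng)
        sp = sample_variant(variants["sp"][variant], rng)
    else:
        maker = make_triangular if variant == "triangular" else make_augmented_triangular
        hs = maker()
        sp = maker()
    return {
        "sp_left": sp,
        "hs_left": hs,
        "neck": sine_pattern(),
        "hs_right": hs,
        "sp_right": sp,
    }


def ablation_changes_only_amplitude_and_offset() -> bool:
    """Check that the resolved ablated network differs from the intact one
    exclusively in the oscillator amplitudes mu and offsets C."""
    intact = default_network("intact")
    ablated = default_network("ablated")
    if intact.edges != ablated.edges:
        return False
    for p, q in zip(intact.oscillators, ablated.oscillators):
        d1 = dataclasses.asdict(p)
        d2 = dataclasses.asdict(q)
        for key in d1:
            if key in ("mu", "C", "U", "L_sd"):
                continue  # amplitude statistics and offset
            if d1[key] != d2[key]:
                return False
    return True


def silence_neck(spec: NetworkSpec) -> NetworkSpec:
    """Zero the neck oscillator amplitude (the joint stays phase-coupled but
    does not move); used by the waveform phase-sensitivity tests, which
    isolate the two antennal joints."""
    osc = list(spec.oscillators)
    osc[2] = replace(osc[2], mu=0.0, U=0.0, L_sd=0.0)
    return replace(spec, oscillators=tuple(osc))


def _with_phase_lead(spec: NetworkSpec, lead_deg: float) -> NetworkSpec:
    """Replace the intra-antennal phase biases so the SP oscillators lead
    their HS oscillators by ``lead_deg`` on both sides."""
    lead = np.deg2rad(lead_deg)
    edges: list[CouplingEdge] = []
    keep = {(e.source, e.target) for pair in ((0, 1), (3, 4)) for e in coupling_pair(*pair, 1.0, 0.0)}
    w01 = next(e.weight for e in spec.edges if (e.source, e.target) == (1, 0))
    w34 = next(e.weight for e in spec.edges if (e.source, e.target) == (4, 3))
    for e in spec.edges:
        if (e.source, e.target) not in keep:
            edges.append(e)
    edges.extend(coupling_pair(0, 1, w01, -lead))  # theta_1 - theta_0 = -lead
    edges.extend(coupling_pair(3, 4, w34, lead))  # theta_4 - theta_3 = +lead
    return replace(spec, edges=tuple(edges))


def _analyze_trial(result: TrialResult) -> dict:
    hs = result.joint("hs_left")
    sp = result.joint("sp_left")
    cg = analysis.sliding_crosscorr(hs, sp, fs=result.fs)
    f_dom = analysis.dominant_frequency(hs, result.fs)
    lag, corr = cg.peak()
    try:
        phase = analysis.peak_phase(cg, f_dom)
    except ValueError:
        phase = float("nan")
    wr_hs = analysis.working_range(hs)
    wr_sp = analysis.working_range(sp)
    ratio, orientation = analysis.trajectory_shape(result.tips_left)
    # in-model phase difference between the SP and HS oscillators
    k_sp = OSCILLATOR_NAMES.index("sp_left")
    k_hs = OSCILLATOR_NAMES.index("hs_left")
    dphi = result.theta[:, k_sp] - result.theta[:, k_hs]
    return {
        "f_dom_hz": f_dom,
        "peak_lag_s": lag,
        "peak_corr": corr,
        "sp_lead_deg": phase,
        "working_range_hs": [wr_hs.lower, wr_hs.upper],
        "working_range_sp": [wr_sp.lower, wr_sp.upper],
        "working_range_hs_width": wr_hs.width,
        "working_range_sp_width": wr_sp.width,
        "shape_ratio": ratio,
        "shape_orientation_rad": orientation,
        "oscillator_phase_circvar": analysis.circular_variance(np.mod(dphi, 2 * np.pi)),
        "oscillator_phase_mean_deg": float(
            np.rad2deg(analysis.circular_mean(dphi))
        ),
        "_correlogram": cg,
    }


def run_condition(
    config: ExperimentConfig,
    chain: KinematicChain | None = None,
    servo: ServoConfig | None = None,
) -> dict:
    """Run one condition/variant and apply the standard analysis suite.

    Returns a summary dict (working ranges, correlogram peak, SP lead,
    trajectory shape); with ``config.outdir`` set, writes the trial CSV,
    the correlogram matrix CSV and the summary JSON.
    """
    spec = config.resolve_network()
    rng = np.random.default_rng(config.seed)
    patterns = resolve_patterns(config.variant, rng)
    log.info(
        "run_condition condition=%s variant=%s seed=%s duration=%s",
        config.condition, config.variant, config.seed, config.duration,
    )
    result = simulate_trial(
        spec,
        patterns,
        chain=chain,
        servo=servo,
        duration=config.duration,
        transient=config.transient,
        rng=rng,
    )
    summary = _analyze_trial(result)
    cg = summary.pop("_correlogram")
    summary.update(
        condition=config.condition,
        variant=config.variant,
        seed=config.seed,
        duration=config.duration,
        transient=config.transient,
        hs_tracking_rmse_deg=result.tracking_rmse("hs_left"),
        sp_tracking_rmse_deg=result.tracking_rmse("sp_left"),
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"{config.condition}_{config.variant}_seed{config.seed}"
        result.to_csv(outdir / f"trial_{tag}.csv")
        cg.to_dataframe().to_csv(outdir / f"correlogram_{tag}.csv")
        with open(outdir / f"summary_{tag}.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    summary["_result"] = result
    summary["_correlogram"] = cg
    return summary


def run_phase_sweep(
    config: ExperimentConfig,
    chain: KinematicChain | None = None,
    servo: ServoConfig | None = None,
) -> pd.DataFrame:
    """Sweep the SP-vs-HS phase lead and record trajectory shape and the
    recovered phase per lead.

    Each lead is run with the same seed and patterns, so rows differ only
    in the imposed phase bias; the table is written to
    ``<outdir>/phase_sweep_<variant>.csv`` if an output directory is set.

    The Mc/Mm sweeps run the full quasi-rhythmic model; the triangular and
    augmented waveform sweeps are deterministic control experiments with the
    neck silenced, isolating the phase relation of the two antennal joints.
    """
    if config.variant == "Mmsd":
        raise ValueError("phase sweep expects a deterministic pattern variant")
    base_spec = config.resolve_network()
    if config.variant in ("triangular", "augmented"):
        base_spec = silence_neck(base_spec.deterministic())
    patterns = resolve_patterns(config.variant, np.random.default_rng(config.seed))
    rows = []
    for lead in config.phase_leads:
        spec = _with_phase_lead(base_spec, float(lead))
        result = simulate_trial(
            spec,
            patterns,
            chain=chain,
            servo=servo,
            duration=config.duration,
            transient=config.transient,
            seed=config.seed,
        )
        summary = _analyze_trial(result)
        rows.append(
            {
                "phase_lead_deg": float(lead),
                "shape_ratio": summary["shape_ratio"],
                "sp_lead_deg": summary["sp_lead_deg"],
                "peak_lag_s": summary["peak_lag_s"],
                "peak_corr": summary["peak_corr"],
            }
        )
        log.info("phase sweep lead=%s shape_ratio=%.3f", lead, summary["shape_ratio"])
    table = pd.DataFrame(rows)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"phase_sweep_{config.variant}.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# configuration files


def load_config(path) -> dict:
    """Load a YAML experiment/network configuration.

    Recognized top-level keys: ``experiment`` (ExperimentConfig fields) and
    ``network`` (oscillator/edge dictionaries, see
    :func:`antcpg.rhythm_core.network_from_dict`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "network" in raw:
        out["network"] = network_from_dict(raw["network"])
    if "experiment" in raw:
        exp = dict(raw["experiment"])
        if "phase_leads" in exp:
            exp["phase_leads"] = tuple(exp["phase_leads"])
        out["experiment"] = exp
    return out
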