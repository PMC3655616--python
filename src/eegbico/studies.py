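"""Packaged synthetic validation studies.

The incision/EA study builds, for each simulated rat, three sessions of
synthetic EEG with known ground truth:

* ``before``   — 1/f background plus five canonical band components
  (delta dominant, as in quiet-resting rodent EEG);
* ``after``    — the postincisional state: the delta component attenuated,
  theta/alpha/beta components strengthened with total power held roughly
  constant, the gamma component untouched, and quadratically phase-coupled
  triplets added whose sum frequencies fall in alpha and beta
  ((4,6)->10, (6,10)->16, (6,17)->23, (10,15)->25 Hz);
* ``ea``       — the post-treatment state: the beta component restored to
  its baseline amplitude and the beta-sum triplets removed, everything
  else as in ``after``.

Component amplitudes are jittered per rat and session (lognormal,
sigma = 0.15) to emulate session-to-session state variability; without it
the between-rat variance would be estimation noise only and even trivial
systematic shifts would reach significance. These settings are the study
conditions; they are fixed here, not tuning knobs.
"""

from __future__ import annotations

import numpy as np

from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .preprocess import Recording
from .synth import SynthSpec, build_recording

__all__ = ["INCISION_EA_CONDITIONS", "make_incision_ea_sessions", "run_incision_ea_study"]

#: (center Hz, bandwidth Hz) of the five band-limited components
BAND_COMPONENTS = {
    "delta": (2.5, 2.0),
    "theta": (6.0, 2.0),
    "alpha": (10.0, 3.0),
    "beta": (20.0, 8.0),
    "gamma": (37.0, 8.0),
}

#: per-session component RMS (uV) and QPC triplets (f1, f2, strength, amp)
INCISION_EA_CONDITIONS = {
    "before": {
        "rms": {"delta": 8.0, "theta": 4.0, "alpha": 3.0, "beta": 2.5, "gamma": 2.0},
        "triplets": [],
    },
    "after": {
        "rms": {"delta": 3.5, "theta": 5.0, "alpha": 3.5, "beta": 3.2, "gamma": 2.0},
        "triplets": [
            (4.0, 6.0, 0.9, 2.5),
            (6.0, 10.0, 0.9, 2.5),
            (6.0, 17.0, 0.9, 2.5),
            (10.0, 15.0, 0.9, 2.5),
        ],
    },
    "ea": {
        "rms": {"delta": 3.5, "theta": 5.0, "alpha": 3.5, "beta": 2.5, "gamma": 2.0},
        "triplets": [(4.0, 6.0, 0.9, 2.5)],
    },
}

BACKGROUND_RMS = 10.0
JITTER_SIGMA = 0.15


def make_incision_ea_sessions(
    n_rats: int = 8,
    duration: float = 60.0,
    fs: float = 256.0,
    n_channels: int = 14,
    seed: int = 0,
) -> dict[str, list[Recording]]:
    """Synthesize the three-session study, one recording per rat per session."""
    ss = np.random.SeedSequence(seed)
    out: dict[str, list[Recording]] = {}
    for session, cond in INCISION_EA_CONDITIONS.items():
        out[session] = []
        for _rat in range(n_rats):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child.generate_state(1)[0] % 2**31)
            jit = lambda: float(np.exp(rng.normal(0.0, JITTER_SIGMA)))  # noqa: E731
            comps = [
                (BAND_COMPONENTS[b][0], BAND_COMPONENTS[b][1], cond["rms"][b] * jit(), None)
                for b in BAND_COMPONENTS
            ]
            spec = SynthSpec(
                n_channels=n_channels,
                fs=fs,
                duration=duration,
                background_slope=1.0,
                background_rms=BACKGROUND_RMS * jit(),
                band_components=comps,
                qpc_triplets=list(cond["triplets"]),
                seed=int(rng.integers(2**31)),
                session_tag=session,
            )
            out[session].append(build_recording(spec))
    return out


def run_incision_ea_study(
    n_rats: int = 8,
    duration: float = 60.0,
    seed: int = 0,
    bico_channels: list[str] | None = None,
    surrogates: int = 0,
) -> PipelineResult:
    """Run the full pipeline on the synthetic incision/EA study.

    Bicoherence is computed on a four-channel subset by default (the
    band-pair statistic is channel-averaged per rat, so a subset changes
    cost, not the statistical unit); the band-pair comparison uses the
    unfiltered bicoherence unless ``surrogates`` > 0.
    """
    recordings = make_incision_ea_sessions(n_rats=n_rats, duration=duration, seed=seed)
    cfg = PipelineConfig(
        surrogates=surrogates,
        bico_channels=bico_channels or ["FL1", "FR2", "PL1", "RPR"],
        comparisons=[("after", "before"), ("ea", "after")],
        seed=seed,
    )
    return run_pipeline(cfg, recordings)


def band_change_tests(result: PipelineResult, after: str, before: str):
    """Paired t-tests on channel-averaged relative band power per rat.

    Returns a DataFrame (band, mean_after, mean_before, t, p, significant).
    """
    import pandas as pd

    from .stats import paired_t

    bp = result.band_power_long
    rows = []
    for band in bp["band"].unique():
        vals = {}
        for tag in (after, before):
            sub = bp[(bp["session"] == tag) & (bp["band"] == band)]
            vals[tag] = sub.groupby("unit")["relative"].mean().sort_index().values
        cmp = paired_t(vals[after], vals[before])
        rows.append(
            {
                "band": band,
                "mean_after": float(np.mean(vals[after])),
                "mean_before": float(np.mean(vals[before])),
                "t": cmp.statistic,
                "p": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    return pd.DataFrame(rows)
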