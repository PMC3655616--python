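"""End-to-end session analysis: preprocess -> power -> bicoherence -> stats.

A :class:`PipelineConfig` carries every analysis parameter, defaulting to
the standard settings of this pipeline (256 Hz, 1-45 Hz band-pass, 2-s
epochs with 75% overlap, 0.5 Hz power grid, 1 Hz / 2 Hz bifrequency grid,
alpha = 0.05). :func:`run_pipeline` takes one recording per experimental
unit (rat) per named session and produces band-power tables, band-pair
coupling tables, session comparisons, and a run manifest sufficient to
replay the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bicoherence import (
    BifrequencyGrid,
    band_pair_table,
    filter_bicoherence,
    surrogate_threshold,
    wavelet_bicoherence,
)
from .preprocess import (
    ParameterError,
    Recording,
    bandpass,
    make_epochs,
    reject_channels,
    reject_epochs,
    rereference_average,
    resample,
)
from .spectral import (
    BandPowerTable,
    CANONICAL_BANDS,
    FrequencyGrid,
    band_power,
    change_rate,
    morlet_power,
)
from .stats import per_channel_screen, wilcoxon_ranksum

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the pipeline's standard settings."""

    rate: float = 256.0
    band_lo: float = 1.0
    band_hi: float = 45.0
    epoch_length: float = 2.0
    overlap: float = 0.75
    power_step: float = 0.5
    omega: float = 6.0
    bifreq_lo: float = 1.0
    bifreq_hi: float = 45.0
    bifreq_step: float = 1.0
    bifreq_bandwidth: float = 2.0
    surrogates: int = 40
    alpha: float = 0.05
    seed: int = 0
    amp_limit: float = 1000.0
    flat_limit: float = 0.01
    epoch_ptp_factor: float = 6.0
    square_coupling: bool = False
    bico_channels: list[str] | None = None  # None = all retained channels
    comparisons: list[tuple[str, str]] = field(default_factory=list)  # (after, before)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ParameterError("overlap must lie in [0, 1)")
        if not (0 < self.band_lo < self.band_hi < self.rate / 2):
            raise ParameterError("band-pass limits invalid for the analysis rate")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.surrogates < 0:
            raise ParameterError("surrogate count must be >= 0")

    @property
    def power_grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.band_lo, self.band_hi, self.power_step)

    @property
    def bifreq_grid(self) -> BifrequencyGrid:
        return BifrequencyGrid(
            self.bifreq_lo, self.bifreq_hi, self.bifreq_step, self.bifreq_bandwidth
        )

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return d


@dataclass
class PipelineResult:
    band_power_long: pd.DataFrame
    coupling_long: pd.DataFrame
    change_rates: dict[tuple[str, str], pd.DataFrame]
    power_screens: dict[tuple[str, str], pd.DataFrame]
    coupling_tests: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write all tables as CSV plus the JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.band_power_long.to_csv(out / "band_power.csv", index=False)
        self.coupling_long.to_csv(out / "band_pair_coupling.csv", index=False)
        for (a, b), df in self.change_rates.items():
            df.to_csv(out / f"change_rate_{a}_vs_{b}.csv")
        for (a, b), df in self.power_screens.items():
            df.to_csv(out / f"power_screen_{a}_vs_{b}.csv", index=False)
        self.coupling_tests.to_csv(out / "coupling_tests.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2,
                                                      default=str))


def _preprocess_one(rec: Recording, cfg: PipelineConfig):
    rec = resample(rec, cfg.rate)
    rec = bandpass(rec, cfg.band_lo, cfg.band_hi)
    rec = rereference_average(rec)
    rec, report = reject_channels(rec, cfg.amp_limit, cfg.flat_limit)
    epochs = make_epochs(rec, cfg.epoch_length, cfg.overlap)
    epochs, _ = reject_epochs(epochs, cfg.epoch_ptp_factor)
    return epochs, report


def run_pipeline(
    config: PipelineConfig,
    recordings: dict[str, list[Recording]],
) -> PipelineResult:
    """Run the full analysis over sessions of per-unit recordings.

    ``recordings`` maps a session tag to a list of recordings, one per
    experimental unit, in the same unit order across sessions. Band-pair
    coupling is channel-averaged per unit (the unit, not the channel, is
    the statistical sample) and compared across sessions with Wilcoxon
    rank-sum; band powers are compared per (channel, band) with paired t.
    """
    if not recordings or any(len(v) == 0 for v in recordings.values()):
        raise ParameterError("need at least one recording per named session")
    sessions = list(recordings)
    rng = np.random.SeedSequence(config.seed)

    band_rows: list[pd.DataFrame] = []
    coupling_rows: list[pd.DataFrame] = []
    band_tables: dict[str, list[BandPowerTable]] = {s: [] for s in sessions}
    errors_ctx = "{stage} failed for session={session} unit={unit}: {err}"

    for session in sessions:
        for unit, rec in enumerate(recordings[session]):
            try:
                epochs, _ = _preprocess_one(rec, config)
            except Exception as err:  # annotate with stage + input identity
                raise RuntimeError(
                    errors_ctx.format(stage="preprocess", session=session,
                                      unit=unit, err=err)
                ) from err
            epochs.session_tag = session
            spec = morlet_power(epochs, config.power_grid, config.omega)
            bp = band_power(spec, CANONICAL_BANDS)
            band_tables[session].append(bp)
            long = bp.to_frame()
            long.insert(1, "unit", unit)
            band_rows.append(long)

            chans = config.bico_channels or epochs.labels
            for ch in chans:
                if ch not in epochs.labels:
                    continue
                bic = wavelet_bicoherence(epochs, ch, config.bifreq_grid)
                if config.surrogates > 0:
                    thr = surrogate_threshold(
                        epochs, ch, config.bifreq_grid,
                        n_surrogates=config.surrogates, alpha=config.alpha,
                        seed=rng.spawn(1)[0].generate_state(1)[0] % 2**31,
                    )
                    bic = filter_bicoherence(bic, thr)
                tbl = band_pair_table(bic, CANONICAL_BANDS, config.square_coupling)
                tbl.insert(0, "unit", unit)
                coupling_rows.append(tbl)

    band_power_long = pd.concat(band_rows, ignore_index=True)
    coupling_long = pd.concat(coupling_rows, ignore_index=True)

    change_rates: dict[tuple[str, str], pd.DataFrame] = {}
    power_screens: dict[tuple[str, str], pd.DataFrame] = {}
    test_rows = []
    unit_coupling = (
        coupling_long.groupby(["session", "unit", "band_j", "band_k"])["coupling"]
        .mean()
        .reset_index()
    )
    for after_tag, before_tag in config.comparisons:
        for tag in (after_tag, before_tag):
            if tag not in recordings:
                raise ParameterError(f"comparison session {tag!r} not provided")
        # mean change rate across units (channel x band), one table per pair
        rates = [
            change_rate(a, b)
            for a, b in zip(band_tables[after_tag], band_tables[before_tag])
            if a.relative.index.equals(b.relative.index)
        ]
        if rates:
            change_rates[(after_tag, before_tag)] = (
                sum(rates) / len(rates)
            )
        screen_in = {}
        for tag in (after_tag, before_tag):
            long = band_power_long[band_power_long["session"] == tag]
            screen_in[tag] = long.rename(columns={"relative": "value"})[
                ["unit", "channel", "band", "value"]
            ]
        common = set(map(tuple, screen_in[after_tag][["channel", "band"]].values)) & \
            set(map(tuple, screen_in[before_tag][["channel", "band"]].values))
        for tag in (after_tag, before_tag):
            df = screen_in[tag]
            screen_in[tag] = df[
                df[["channel", "band"]].apply(tuple, axis=1).isin(common)
            ]
        power_screens[(after_tag, before_tag)] = per_channel_screen(
            screen_in[after_tag], screen_in[before_tag], alpha=config.alpha
        )
        for (bj, bk), grp in unit_coupling.groupby(["band_j", "band_k"]):
            xa = grp[grp["session"] == after_tag]["coupling"].dropna().values
            xb = grp[grp["session"] == before_tag]["coupling"].dropna().values
            if len(xa) < 1 or len(xb) < 1:
                continue
            try:
                cmp = wilcoxon_ranksum(xa, xb, alpha=config.alpha)
                stat, p = cmp.statistic, cmp.p_value
            except ValueError:
                stat, p = np.nan, 1.0
            test_rows.append(
                {
                    "after": after_tag, "before": before_tag,
                    "band_j": bj, "band_k": bk,
                    "median_after": float(np.median(xa)) if len(xa) else np.nan,
                    "median_before": float(np.median(xb)) if len(xb) else np.nan,
                    "statistic": stat, "p": p,
                    "significant": p < config.alpha,
                }
            )
    coupling_tests = pd.DataFrame(test_rows)

    manifest = {
        "config": config.to_manifest(),
        "sessions": {s: len(recordings[s]) for s in sessions},
        "versions": _versions(),
        "decisions": {
            "filter": "zero-phase elliptic band-pass (ellipord-sized)",
            "wavelet_normalization": "unit gain at center frequency",
            "coupling_values": "squared-normalized bicoherence"
            + (", re-squared in band sums" if config.square_coupling else ""),
            "bicoherence_filter": (
                f"surrogate 1-alpha quantile, {config.surrogates} surrogates"
                if config.surrogates > 0 else "unfiltered"
            ),
            "multiplicity": "uncorrected per-channel tests",
        },
    }
    return PipelineResult(
        band_power_long=band_power_long,
        coupling_long=coupling_long,
        change_rates=change_rates,
        power_screens=power_screens,
        coupling_tests=coupling_tests,
        manifest=manifest,
    )


def _versions() -> dict:
    import scipy

    return {
        "eegbico": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
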