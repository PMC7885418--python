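"""End-to-end synthetic study: calibrate both controllers for a simulated
subject and compare them on the closed-loop target-acquisition test.

Defaults are scaled down (shorter cue protocol, narrower network, fewer
optimizer iterations) so a full multi-subject comparison runs in minutes
on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration as cal
from . import envelope as envmod
from . import fitts, lda, metrics, network, synth

LOOP_PROTOCOL = synth.AcquisitionProtocol(
    repetitions=2, movement_duration=2.5, rest_duration=1.5
)
LOOP_TOPOLOGY = network.Topology(
    first_layer_log2=5, encoder_depth=3, decoder_hidden_log2=4
)
LOOP_USER = dict(
    direction_noise_sd=0.15, magnitude_noise_sd=0.08, smoothing=0.9, ramp_px=250
)


def loop_training_config(seed: int) -> cal.TrainingConfig:
    return cal.TrainingConfig(
        batch_size=256, max_iterations=700, lookback=600,
        learning_rate=3e-3, seed=seed,
    )


@dataclass
class SubjectAssets:
    """Everything calibrated for one simulated subject."""

    profile: synth.SubjectProfile
    stats: envmod.NormalizationStats
    filter_length: int
    net_params: network.NetParams
    net_log: cal.TrainingLog
    lda_model: lda.LdaModel
    tables: lda.ProportionalityTables


def calibrate_subject(seed: int, protocol=LOOP_PROTOCOL, topology=LOOP_TOPOLOGY,
                      config=None, collapse_threshold: float = 0.5,
                      max_restarts: int = 2) -> SubjectAssets:
    """Generate a calibration session and fit both controllers.

    The L1 objective has a flat all-zero-output region; runs that stop
    there (best validation loss above ``collapse_threshold``) are
    restarted with a fresh initialization, as a practitioner would.
    """
    profile = synth.make_subject_profile(seed)
    rng = np.random.default_rng(seed)
    rec, stim = synth.generate_calibration_session(profile, protocol, rng)
    env, stats = envmod.preprocess(rec)

    best = None
    for attempt in range(max_restarts + 1):
        cfg = config if config is not None else loop_training_config(
            seed + 101 * attempt
        )
        params, log = cal.calibrate(env.values, stim.values, topology, cfg)
        if best is None or min(log.validation) < min(best[1].validation):
            best = (params, log)
        if min(log.validation) <= collapse_threshold:
            break
        config = None  # force a reseeded config on retry
    params, log = best

    model, tables = lda.calibrate_from_session(rec, stim)
    return SubjectAssets(
        profile=profile,
        stats=stats,
        filter_length=env.filter_length,
        net_params=params,
        net_log=log,
        lda_model=model,
        tables=tables,
    )


def run_comparison(assets: SubjectAssets, session_seed: int,
                   user_kwargs: dict | None = None
                   ) -> dict[str, metrics.MetricSet]:
    """One 40-target session per controller with matched user noise."""
    targets = fitts.make_target_set()
    out = {}
    controllers = {
        "regressor": fitts.RegressorController(
            assets.net_params, assets.stats, assets.filter_length
        ),
        "lda": fitts.LdaController(
            assets.lda_model, assets.tables, assets.profile.n_channels
        ),
    }
    for name, ctrl in controllers.items():
        user = fitts.SimulatedUser(**(user_kwargs or LOOP_USER))
        logs = fitts.run_session(ctrl, targets, user, assets.profile, session_seed)
        out[name] = metrics.session_metrics(logs)
    return out
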