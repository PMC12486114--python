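"""Canned experiment configurations at desk scale.

Two reference scenarios drive validation of the whole pipeline:

* ``strong_signal_config``: perfectly consistent outcomes across visits and
  a large oscillator-amplitude separation between responder and
  non-responder traits — the regime where the selected model must recover
  the injected complexity/label association on the external set.
* ``drift_config``: identical feature-generating process but only 50%
  outcome consistency across visits — stable feature distributions with
  unreliable outcomes, the concept-drift signature: high cross-validated
  accuracy on initial visits that fails to transfer to retests.

Both use a reduced search grid (2 classifiers x LM ROI x 1 transform x a
handful of windows) so a full run fits in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEMO_WINDOWS = [[15, 80], [100, 131], [105, 135], [25, 55], [55, 85], [200, 230]]

DEMO_SEARCH = {
    "classifiers": ["lda_lw", "dt"],
    "rois": ["LM"],
    "transforms": ["log_distance"],
    "feature_sets": [("complexity", "disten_m2_coarse"),
                     ("complexity", "permen_m3"),
                     ("band", "alpha"), ("band", "beta")],
    "methods": ["LMFP_T5_100-131"],
    "n_repeats": 3,
    "n_boot": 500,
}

DEMO_FEATURES = {
    "measures": ["disten_m2_coarse", "permen_m3"],
    "channels": ["C1", "C3", "C5", "FC1", "FC3", "FC5"],
}


def strong_signal_config(seed: int, out_dir) -> dict:
    return {
        "seed": int(seed),
        "out_dir": str(out_dir),
        "experiment": "LMFP",
        "design": "cross_session",
        "cohort": {
            "cohort1_counts": (10, 0, 0), "cohort2_counts": (10, 0, 0),
            "label_consistency": 1.0, "responder_osc_scale": 2.0,
            "channel_noise": 1.0,
        },
        "features": dict(DEMO_FEATURES),
        "windows": [list(w) for w in DEMO_WINDOWS],
        "search": dict(DEMO_SEARCH),
    }


def drift_config(seed: int, out_dir) -> dict:
    cfg = strong_signal_config(seed, out_dir)
    cfg["cohort"]["cohort1_counts"] = (15, 0, 0)
    cfg["cohort"]["cohort2_counts"] = (15, 0, 0)
    cfg["cohort"]["label_consistency"] = 0.5
    return cfg


def null_calibration(seed: int, n_units: int = 1000,
                     visit_sizes: tuple = (200, 200),
                     mep_trials: int = 60) -> dict:
    """Type-I-error calibration of the labelling and shift tests.

    Simulates ``n_units`` independent units under the null: MEP sessions
    with zero injected effect (responder rate should be ~alpha), features
    drawn identically on both visits (KS rejection ~alpha) and outcome
    labels with identical class probabilities on both visits (Fisher
    rejection ~alpha, noting the test's conservatism on small tables —
    hence per-visit sizes large enough for the discreteness to be mild).
    """
    from neuromodml.outcomes import mep_ttest_label
    from neuromodml.reliability import fisher_exact_2x2, ks_two_sample
    from neuromodml.rng import substream
    from neuromodml.synthetic import CohortSpec, generate_mep_block

    spec = CohortSpec(mep_effect_size=0.0)
    rng = substream(seed, "null-calibration")
    n1, n2 = visit_sizes
    mep_hits = ks_hits = fisher_hits = 0
    for u in range(n_units):
        pre = generate_mep_block(spec, "pre", False, int(rng.integers(2 ** 31)),
                                 n_trials=mep_trials)
        post = generate_mep_block(spec, "T5", False, int(rng.integers(2 ** 31)),
                                  n_trials=mep_trials)
        mep_hits += mep_ttest_label(pre, post).label

        _, p = ks_two_sample(rng.standard_normal(n1), rng.standard_normal(n2))
        ks_hits += p <= 0.05

        a = rng.random(n1) < 0.5
        b = rng.random(n2) < 0.5
        table = [[int(a.sum()), int(n1 - a.sum())],
                 [int(b.sum()), int(n2 - b.sum())]]
        fisher_hits += fisher_exact_2x2(table) <= 0.05
    return {
        "mep_responder_rate": mep_hits / n_units,
        "ks_rejection_rate": ks_hits / n_units,
        "fisher_rejection_rate": fisher_hits / n_units,
        "n_units": n_units,
    }


def permuted_label_accuracies(seed: int, n_train: int = 60, n_val: int = 40,
                              n_features: int = 6, n_reps: int = 3) -> dict:
    """External accuracy of every classifier under permuted labels.

    Features carry no label information by construction; any classifier
    whose external accuracy escapes chance bounds indicates leakage between
    the training pipeline and the validation set.
    """
    from neuromodml.models import classifier_registry, external_validate
    from neuromodml.rng import substream

    registry = classifier_registry()
    out = {}
    for cid, factory in registry.items():
        accs = []
        for rep in range(n_reps):
            rng = substream(seed, "leakage", cid, rep)
            cols = [f"f{i}" for i in range(n_features)]
            x_tr = pd.DataFrame(
                np.abs(rng.standard_normal((n_train, n_features))) + 0.1,
                columns=cols)
            x_va = pd.DataFrame(
                np.abs(rng.standard_normal((n_val, n_features))) + 0.1,
                columns=cols)
            y_tr = rng.permutation(np.repeat([0, 1], n_train // 2))
            y_va = rng.permutation(np.repeat([0, 1], n_val // 2))
            res = external_validate(factory, "zscore", x_tr, y_tr,
                                    x_va, y_va, seed + rep, n_boot=20)
            accs.append(res.point["accuracy"])
        out[cid] = float(np.mean(accs))
    return out
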