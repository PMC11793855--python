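"""End-to-end orchestration: traces -> indexes -> features -> classifier.

The functions here are thin glue over the per-stage modules; they are what
the command-line interface and the reproduction script call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import evaluation
from .indexes import FEATURE_NAMES, IndexWindows, compute_indexes
from .optics import ProbeGeometry, process_trace
from .protocol import ProtocolError, PressureTrace, segment_protocol
from .rbfnn import RBFNetClassifier, split_trials
from .synthetic import TrialRecord

logger = logging.getLogger(__name__)

INDEX_COLUMNS = [
    "index_i", "index_ii", "index_iii", "index_iv", "index_v", "index_vi", "index_vii",
]


def process_trial(
    pressure: PressureTrace,
    optical,
    geometry: ProbeGeometry,
    protocol_kwargs: dict | None = None,
    windows: IndexWindows = IndexWindows(),
    sto2_floor: float = 1e-9,
) -> dict[str, object]:
    """Segment one trial and extract HbT and StO2 index sets."""
    seg = segment_protocol(pressure, **(protocol_kwargs or {}))
    hemo = process_trace(optical, geometry, denominator_floor=sto2_floor)
    return {
        "segmentation": seg,
        "hemo": hemo,
        "HbT": compute_indexes(hemo, seg, "HbT", windows),
        "StO2": compute_indexes(hemo, seg, "StO2", windows),
    }


def trials_to_index_table(
    trials: list[TrialRecord],
    geometry: ProbeGeometry,
    protocol_kwargs: dict | None = None,
    windows: IndexWindows = IndexWindows(),
    sto2_floor: float = 1e-9,
) -> pd.DataFrame:
    """Long-format index table: one row per trial per signal.

    Trials that fail segmentation are logged and excluded; the count of
    exclusions is attached as ``df.attrs['n_failed']``.
    """
    rows = []
    n_failed = 0
    for tr in trials:
        try:
            res = process_trial(
                tr.pressure, tr.optical, geometry, protocol_kwargs, windows, sto2_floor
            )
        except (ProtocolError, ValueError) as exc:
            n_failed += 1
            logger.warning("trial %s/%d excluded: %s", tr.subject_id, tr.trial, exc)
            continue
        for signal in ("HbT", "StO2"):
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "trial": tr.trial,
                    "group": tr.group,
                    "signal": signal,
                    **res[signal].as_dict(),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


def feature_table(index_df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial classifier features from the long-format index table.

    Rows with any undefined feature component are dropped (logged). Columns:
    ``subject_id, trial, group`` plus the five feature names.
    """
    rows = []
    for (subject, trial), sub in index_df.groupby(["subject_id", "trial"]):
        by_signal = {s.signal: s for s in sub.itertuples()}
        if "HbT" not in by_signal or "StO2" not in by_signal:
            logger.warning("trial %s/%s lacks a signal; dropped", subject, trial)
            continue
        h, s = by_signal["HbT"], by_signal["StO2"]
        vec = np.array([h.index_i, h.index_ii, h.index_iii, h.index_vi, s.index_vii])
        if np.any(np.isnan(vec)):
            logger.warning("trial %s/%s has undefined indexes; dropped", subject, trial)
            continue
        rows.append(
            {"subject_id": subject, "trial": trial, "group": h.group,
             **dict(zip(FEATURE_NAMES, vec))}
        )
    return pd.DataFrame(rows)


def make_classifier(cfg_classifier: dict, random_state=None) -> Pipeline:
    """Feature z-scoring (training statistics) followed by the RBF network."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "rbf",
                RBFNetClassifier(
                    n_hidden=cfg_classifier.get("n_hidden", 64),
                    threshold=cfg_classifier.get("threshold", 0.5),
                    width=cfg_classifier.get("width", "data"),
                    lms_step=cfg_classifier.get("lms_step", 0.05),
                    lms_epochs=cfg_classifier.get("lms_epochs", 200),
                    lms_eps=cfg_classifier.get("lms_eps", 1e-8),
                    random_state=random_state,
                ),
            ),
        ]
    )


def train_eval(
    features: pd.DataFrame,
    cfg_classifier: dict | None = None,
    seed: int | np.random.Generator = 0,
    good_group: str = "I",
    poor_group: str = "IV",
) -> tuple[dict, Pipeline]:
    """Train the classifier on good/poor groups and evaluate on held-out trials.

    Splits the good (desired output 0) and poor (desired output 1) trials
    into train/test sets — by default 35+35 training and 15+15 test trials
    with no subject on both sides — fits the scaler and RBF network on the
    training split, and reports the four evaluation metrics for both stages
    plus mean fuzzy outputs per clinical group.
    """
    cfg = cfg_classifier or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    binary = features[features["group"].isin([good_group, poor_group])].reset_index(drop=True)
    X = binary[list(FEATURE_NAMES)].to_numpy()
    y = binary["group"].to_numpy()
    train_idx, test_idx = split_trials(
        binary["subject_id"].to_numpy(),
        y,
        train_per_class=cfg.get("train_per_class", 35),
        test_per_class=cfg.get("test_per_class", 15),
        level=cfg.get("split_level", "subject"),
        rng=rng,
    )
    model = make_classifier(cfg, random_state=rng)
    model.fit(X[train_idx], y[train_idx])

    report: dict = {"n_train": len(train_idx), "n_test": len(test_idx)}
    for stage, idx in (("training", train_idx), ("test", test_idx)):
        pred = model.predict(X[idx])
        cm = evaluation.confusion_from_predictions(y[idx], pred, positive=good_group)
        report[stage] = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "metrics": evaluation.metrics(cm),
        }
    outputs = {}
    for g, sub in features.groupby("group"):
        out = model.decision_function(sub[list(FEATURE_NAMES)].to_numpy())
        outputs[g] = {
            "mean": float(np.mean(out)),
            "sd": float(np.std(out, ddof=1)) if out.size > 1 else float("nan"),
            "n": int(out.size),
        }
    report["group_outputs"] = outputs
    return report, model
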