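"""Self-contained synthetic studies used for validation and reporting.

Two reference experiments exercise the whole pipeline on phantoms only:

* :func:`synthetic_detection_experiment` — train the CNN on high-contrast
  phantoms and score held-out accuracy and AUC.  Problem sizes default to
  64 training and 40 held-out images at 128 px with 64 px feature stacks,
  a scale one CPU handles in tens of seconds while leaving the task
  non-trivial (five patterns, random spot counts of texture-embedded spots).
* :func:`localization_recovery_experiment` — run top-hat localization on
  seeded positive phantoms and measure the fraction of planted spot centres
  recovered within a pixel radius.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import CNNClassifier
from .evaluate import confusion, localization_score, metrics, roc_auc
from .features import FeatureStackExtractor
from .localize import localize_pipeline
from .phantom import PATTERNS, PhantomSpec, generate_phantom

__all__ = ["synthetic_detection_experiment", "localization_recovery_experiment",
           "DetectionResult"]


@dataclass
class DetectionResult:
    accuracy: float
    auc: float
    n_train: int
    n_test: int
    recall: float | None
    specificity: float | None


def _make_phantoms(n: int, positive: bool, seeds, side: int,
                   spot_contrast: float):
    images = []
    truths = []
    for i, s in enumerate(seeds):
        spec = PhantomSpec(width=side, height=side,
                           n_spots=(3 + int(s) % 5) if positive else 0,
                           spot_contrast=spot_contrast,
                           pattern=PATTERNS[i % len(PATTERNS)],
                           seed=int(s))
        img, truth = generate_phantom(spec)
        images.append(img)
        truths.append(truth)
    return images, truths


def synthetic_detection_experiment(seed: int = 0, n_train: int = 64,
                                   n_test: int = 40, side: int = 128,
                                   stack_side: int = 64,
                                   spot_contrast: float = 0.5,
                                   epochs: int = 20,
                                   learning_rate: float = 1e-3
                                   ) -> DetectionResult:
    """Train on balanced high-contrast phantoms, score a held-out set."""
    rng = np.random.default_rng(seed)
    n_half_tr, n_half_te = n_train // 2, n_test // 2
    seeds = rng.integers(0, 2**31 - 1, size=n_train + n_test)
    tr_pos, _ = _make_phantoms(n_half_tr, True, seeds[:n_half_tr], side, spot_contrast)
    tr_neg, _ = _make_phantoms(n_half_tr, False, seeds[n_half_tr:n_train], side, spot_contrast)
    te_pos, _ = _make_phantoms(n_half_te, True,
                               seeds[n_train:n_train + n_half_te], side, spot_contrast)
    te_neg, _ = _make_phantoms(n_half_te, False,
                               seeds[n_train + n_half_te:], side, spot_contrast)

    fx = FeatureStackExtractor(out_side=stack_side)
    X_train = fx.transform(tr_pos + tr_neg)
    y_train = np.array([1] * len(tr_pos) + [0] * len(tr_neg))
    X_test = fx.transform(te_pos + te_neg)
    y_test = np.array([1] * len(te_pos) + [0] * len(te_neg))

    clf = CNNClassifier(learning_rate=learning_rate, epochs=epochs,
                        batch_size=8, dropout=0.2, l2=0.001,
                        random_state=seed)
    clf.fit(X_train, y_train)
    prob = clf.predict_proba(X_test)[:, 1]
    pred = (prob > 0.5).astype(int)
    rep = metrics(confusion(pred, y_test))
    _, auc = roc_auc(prob, y_test)
    return DetectionResult(accuracy=float(np.mean(pred == y_test)), auc=float(auc),
                           n_train=len(y_train), n_test=len(y_test),
                           recall=rep.recall, specificity=rep.specificity)


def localization_recovery_experiment(seed: int = 0, n_images: int = 20,
                                     side: int = 128, spot_contrast: float = 0.7,
                                     match_radius_px: float = 3.0
                                     ) -> dict[str, float]:
    """Fraction of planted spot centres recovered within ``match_radius_px``.

    Pools matches over ``n_images`` seeded positive phantoms; the SE radius
    per image is the largest planted spot radius + 2 px.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    matched = 0
    total_spots = 0
    total_cands = 0
    for i, s in enumerate(seeds):
        spec = PhantomSpec(width=side, height=side, n_spots=5,
                           spot_contrast=spot_contrast,
                           pattern=PATTERNS[i % len(PATTERNS)], seed=int(s))
        img, truth = generate_phantom(spec)
        max_r = max(sp.diameter_px for sp in truth.spots) / 2.0
        cands, _ = localize_pipeline(img, se_radius=int(np.ceil(max_r)) + 2)
        rec, _, pairs = localization_score(cands, truth,
                                           match_radius_px=match_radius_px)
        matched += len(pairs)
        total_spots += len(truth.spots)
        total_cands += len(cands)
    return {"spot_recall": matched / total_spots,
            "candidate_precision": matched / total_cands if total_cands else float("nan"),
            "n_spots": total_spots, "n_images": n_images}
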