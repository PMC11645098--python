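"""Epoch -> fixed-length feature vectors.

Two recipes: (1) state-space features — the entries of the canonicalized
(A, C, K) matrices of an order-m innovation model identified from the
epoch, concatenated row-major as (a_11..a_mm, c_1..c_m, k_1..k_m), width
m^2 + 2m (35 for the order-5 offline model); (2) the comparison set of
AR(p) Burg coefficients plus level-L wavelet-packet Shannon entropies,
width p + 2^L (20 for p=4, L=4).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sp_signal
from statsmodels.regression.linear_model import burg

from .preprocess import DegenerateInputError, Epoch
from .sysid import DEFAULT_HORIZON, identify

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateSpaceFeatures:
    """Feature recipe: canonical (A, C, K) entries of an order-m model.

    decimate: integer factor by which the epoch is FIR-decimated before
    identification.  The analysis passband tops out at 30 Hz, so epochs
    sampled at 1000 Hz are heavily oversampled and their covariance
    structure is numerically near-singular; identifying on a decimated
    copy conditions the problem without discarding in-band information.
    """

    order: int = 5
    horizon: int = DEFAULT_HORIZON
    decimate: int = 4

    @property
    def width(self) -> int:
        return self.order**2 + 2 * self.order

    @property
    def names(self) -> list[str]:
        m = self.order
        return (
            [f"a_{i + 1}{j + 1}" for i in range(m) for j in range(m)]
            + [f"c_{i + 1}" for i in range(m)]
            + [f"k_{i + 1}" for i in range(m)]
        )


@dataclass(frozen=True)
class ARShannonFeatures:
    """Feature recipe: AR(p) coefficients + level-L wavelet-packet entropies."""

    ar_order: int = 4
    wp_level: int = 4
    wavelet: str = "db4"
    normalized_entropy: bool = True

    @property
    def width(self) -> int:
        return self.ar_order + 2**self.wp_level

    @property
    def names(self) -> list[str]:
        return [f"ar_{i + 1}" for i in range(self.ar_order)] + [
            f"se_{i + 1}" for i in range(2**self.wp_level)
        ]


FeatureSet = StateSpaceFeatures | ARShannonFeatures


@dataclass
class FeatureMatrix:
    """Epochs x features table with labels and provenance."""

    values: pd.DataFrame
    feature_set: FeatureSet
    labels: np.ndarray | None = None
    epoch_refs: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.feature_set.width:
            raise ValueError(
                f"feature matrix width {self.values.shape[1]} != recipe width "
                f"{self.feature_set.width}"
            )
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy()

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = self.values.copy()
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)
        meta = {
            "feature_set": type(self.feature_set).__name__,
            "params": self.feature_set.__dict__,
            "epoch_refs": self.epoch_refs,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Individual feature extractors
# ---------------------------------------------------------------------------

def _samples(epoch: Epoch | np.ndarray) -> np.ndarray:
    return epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)


def state_space_features(
    epoch: Epoch | np.ndarray,
    order: int = 5,
    horizon: int = DEFAULT_HORIZON,
    decimate: int = 4,
) -> np.ndarray:
    """Row-major concatenation of canonical A, then C, then K entries.

    The horizon shrinks automatically when the (decimated) epoch is too
    short to fill the requested covariance Hankel matrix.
    """
    y = _samples(epoch)
    try:
        if len(y) == 0 or np.std(y) < 1e-12 * max(1.0, float(np.max(np.abs(y), initial=0.0))):
            raise DegenerateInputError("constant epoch carries no dynamics")
        if decimate > 1 and len(y) >= 10 * decimate:
            y = sp_signal.decimate(y, decimate, ftype="fir")
        h = min(horizon, (len(y) - 10 * order) // 2)
        if h < order + 1:
            raise DegenerateInputError(
                f"epoch too short for order {order} identification "
                f"({len(y)} samples after decimation)"
            )
        r = identify(y, order, horizon=h, canonical=True)
    except (DegenerateInputError, ValueError) as exc:
        if isinstance(epoch, Epoch):
            raise type(exc)(
                f"{exc} (epoch: subject={epoch.subject_id!r}, "
                f"onset={epoch.onset_index}, window={epoch.window})"
            ) from exc
        raise
    return np.concatenate([r.A.ravel(), r.C.ravel(), r.K.ravel()])


def ar_coefficients(epoch: Epoch | np.ndarray, ar_order: int = 4) -> np.ndarray:
    """Burg-estimated AR coefficients, prediction-weight convention
    (y_t = sum_k a_k y_{t-k} + e_t, positive a_k multiply past samples)."""
    y = _samples(epoch)
    if len(y) <= 10 * ar_order:
        raise DegenerateInputError(
            f"epoch length {len(y)} too short for AR order {ar_order}"
        )
    if np.std(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        raise DegenerateInputError("near-constant epoch: AR model undefined")
    coefs, _sigma2 = burg(y, order=ar_order, demean=True)
    return np.asarray(coefs, dtype=float)


def shannon_entropy(weights: np.ndarray, normalized: bool = True) -> float:
    """Shannon entropy of a coefficient vector.

    normalized: H = -sum p_i log2 p_i with p_i = w_i^2 / sum w^2 (bounded by
    log2 len(w), scale-invariant).  Unnormalized variant: -sum w^2 log(w^2).
    """
    w = np.asarray(weights, dtype=float)
    e = w**2
    total = e.sum()
    if total == 0.0:
        logger.debug("all-zero node: entropy 0 by convention")
        return 0.0
    if normalized:
        p = e / total
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum())
    nz = e > 0
    return float(-(e[nz] * np.log(e[nz])).sum())


def wp_shannon_entropy(
    epoch: Epoch | np.ndarray,
    level: int = 4,
    wavelet: str = "db4",
    normalized: bool = True,
) -> np.ndarray:
    """Shannon entropy of each terminal node of a full wavelet-packet
    decomposition (2^level values, natural node order)."""
    y = _samples(epoch)
    if len(y) < 2**level:
        raise DegenerateInputError(
            f"epoch length {len(y)} < 2^{level} required for wavelet packets"
        )
    wp = pywt.WaveletPacket(y, wavelet, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="natural")
    return np.array([shannon_entropy(n.data, normalized) for n in nodes])


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

def feature_row(epoch: Epoch | np.ndarray, feature_set: FeatureSet) -> np.ndarray:
    if isinstance(feature_set, StateSpaceFeatures):
        return state_space_features(
            epoch, feature_set.order, feature_set.horizon, feature_set.decimate
        )
    return np.concatenate(
        [
            ar_coefficients(epoch, feature_set.ar_order),
            wp_shannon_entropy(
                epoch,
                feature_set.wp_level,
                feature_set.wavelet,
                feature_set.normalized_entropy,
            ),
        ]
    )


def build_feature_matrix(epochs: list[Epoch], feature_set: FeatureSet) -> FeatureMatrix:
    """One feature row per epoch; all epochs must share the same window."""
    if epochs:
        lengths = {len(ep.samples) for ep in epochs}
        if len(lengths) > 1:
            offenders = [
                (ep.subject_id, ep.onset_index, len(ep.samples))
                for ep in epochs
                if len(ep.samples) != len(epochs[0].samples)
            ]
            raise ValueError(f"mixed epoch lengths; offenders: {offenders}")
    rows = [feature_row(ep, feature_set) for ep in epochs]
    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, feature_set.width)),
        columns=feature_set.names,
    )
    labels = (
        np.array([ep.label for ep in epochs], dtype=object) if epochs else None
    )
    refs = [(ep.subject_id, ep.onset_index) for ep in epochs]
    return FeatureMatrix(
        values=values, feature_set=feature_set, labels=labels, epoch_refs=refs
    )
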