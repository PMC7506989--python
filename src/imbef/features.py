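"""Feature construction: locality energies fused with dual state-space models.

For one epoch the feature vector is the concatenation

    [ E_1 .. E_{2^l_LE}  |  s_1  |  s_2 ]

where the E_m are the packet-node energies at level ``level_le`` (wavelet
``wavelet_le``) and s_m = [vec(A_m) row-major, B_m, K_m] are the parameters
of the innovation-form model fitted to the m-th first-level packet
coefficient series (wavelet ``wavelet_dssm``, order ``order_dssm``).  The
total dimension is 2^l_LE + 2^l_SSM (n^2 + 2n); with the single first-level
split (l_SSM = 1, the only case supported here) that is 2^l_LE + 2(n^2+2n) —
128 at the default operating point (l_LE=5, n=6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import EpochMatrix
from .sysid import SSModel, estimate_ssm
from .wpd import SUPPORTED_WAVELETS, locality_energy, wpd_decompose

logger = logging.getLogger(__name__)


class SubbandEstimationError(RuntimeError):
    """Model estimation failed on one first-level sub-band."""

    def __init__(self, subband: int, message: str):
        self.subband = subband
        super().__init__(f"sub-band m={subband}: {message}")


@dataclass(frozen=True)
class FeatureParams:
    """The four tunable feature parameters (plus the fixed split level)."""

    wavelet_dssm: str = "db1"
    order_dssm: int = 6
    wavelet_le: str = "db4"
    level_le: int = 5
    level_ssm: int = 1  # number of packet levels feeding models; fixed at 1

    def __post_init__(self):
        if self.level_ssm != 1:
            raise ValueError("only the first-level dual-model split is supported")
        if not 5 <= self.order_dssm <= 10:
            raise ValueError(f"order_dssm must be in 5..10, got {self.order_dssm}")
        if not 3 <= self.level_le <= 7:
            raise ValueError(f"level_le must be in 3..7, got {self.level_le}")
        for w in (self.wavelet_dssm, self.wavelet_le):
            if w not in SUPPORTED_WAVELETS:
                raise ValueError(
                    f"unsupported wavelet {w!r}; supported: {SUPPORTED_WAVELETS}"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FeatureTable:
    """Per-epoch feature vectors with the parameters that produced them."""

    matrix: np.ndarray  # (L, dim)
    params: FeatureParams
    labels: np.ndarray | None = None
    column_names: tuple = ()
    skipped: tuple = ()  # (row index, reason) for rows dropped on_error="skip"

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        dim = feature_dimension(self.params)
        if matrix.ndim != 2 or matrix.shape[1] != dim:
            raise ValueError(
                f"feature matrix must have {dim} columns for {self.params}"
            )
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            object.__setattr__(self, "labels", labels)
            if labels.shape != (matrix.shape[0],):
                raise ValueError("labels must have one entry per feature row")

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[0]


def feature_dimension(params: FeatureParams) -> int:
    n = params.order_dssm
    return 2 ** params.level_le + 2 ** params.level_ssm * (n * n + 2 * n)


def feature_names(params: FeatureParams) -> tuple:
    n = params.order_dssm
    names = [f"LE_l{params.level_le}_m{m}" for m in range(1, 2 ** params.level_le + 1)]
    for m in (1, 2):
        names += [f"SSM{m}_A_{r}{c}" for r in range(1, n + 1) for c in range(1, n + 1)]
        names += [f"SSM{m}_B_{k}" for k in range(1, n + 1)]
        names += [f"SSM{m}_K_{k}" for k in range(1, n + 1)]
    return tuple(names)


def dssm_features(epoch: np.ndarray, wavelet_dssm: str, order: int,
                  horizon: int | None = None) -> np.ndarray:
    """Parameters of the two models fitted to the first-level sub-bands.

    Output length 2(n^2 + 2n): s_1 then s_2, each laid out as
    [vec(A) row-major, B, K].
    """
    sc = wpd_decompose(np.asarray(epoch, dtype=float), wavelet_dssm, level=1)
    parts = []
    for m, series in enumerate(sc.nodes, start=1):
        try:
            model = estimate_ssm(series, order=order, horizon=horizon)
        except ValueError as err:
            raise SubbandEstimationError(m, str(err)) from err
        parts.append(model.parameter_vector())
    return np.concatenate(parts)


def le_features(epoch: np.ndarray, wavelet_le: str, level_le: int) -> np.ndarray:
    """Locality energies of one epoch (length 2**level_le)."""
    return locality_energy(wpd_decompose(epoch, wavelet_le, level_le)).energies


def build_imbef(epoch: np.ndarray, params: FeatureParams,
                horizon: int | None = None) -> np.ndarray:
    """One epoch's fused feature vector: [LE block, dual-model block]."""
    le = le_features(epoch, params.wavelet_le, params.level_le)
    ssm = dssm_features(epoch, params.wavelet_dssm, params.order_dssm, horizon)
    return np.concatenate([le, ssm])


def extract_features(em: EpochMatrix, params: FeatureParams,
                     on_error: str = "skip") -> FeatureTable:
    """Batch feature extraction over an epoch matrix, row order preserved."""
    if on_error not in ("skip", "fail"):
        raise ValueError("on_error must be 'skip' or 'fail'")
    rows, kept_idx, skipped = [], [], []
    for idx in range(em.n_epochs):
        try:
            rows.append(build_imbef(em.epochs[idx], params))
            kept_idx.append(idx)
        except (SubbandEstimationError, ValueError) as err:
            if on_error == "fail":
                raise RuntimeError(f"feature extraction failed at epoch {idx}: "
                                   f"{err}") from err
            logger.warning("skipping epoch %d: %s", idx, err)
            skipped.append((idx, str(err)))
    if not rows:
        raise ValueError("no epoch yielded features")
    labels = em.labels[kept_idx] if em.labels is not None else None
    return FeatureTable(
        matrix=np.vstack(rows),
        params=params,
        labels=labels,
        column_names=feature_names(params),
        skipped=tuple(skipped),
    )
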