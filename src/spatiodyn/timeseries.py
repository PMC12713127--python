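"""Container for intrinsic connectivity network (ICN) time courses.

The whole pipeline operates on a single in-memory object: a ``T x N`` real
matrix of network time courses (rows = timepoints, columns = ICNs) with a
sampling interval (TR, seconds) and an ordered list of 1-based ICN labels.
Preprocessing steps record themselves in ``flags`` so downstream stages can
check what has been applied without re-deriving it from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

#: Recognised preprocessing flags, in canonical pipeline order.
PREPROCESSING_FLAGS = ("bandpassed", "gsr", "zscored")


@dataclass(frozen=True)
class ICNTimeSeries:
    """A ``T x N`` matrix of ICN time courses sampled every ``tr_seconds``.

    Parameters
    ----------
    data
        Real matrix, shape ``(T, N)``: ``T`` timepoints by ``N`` ICNs.
    tr_seconds
        Sampling interval (repetition time) in seconds; must be positive.
    icn_ids
        Ordered 1-based integer labels for the columns. Defaults to
        ``1..N``.
    flags
        Set of preprocessing flags from :data:`PREPROCESSING_FLAGS`.
    """

    data: np.ndarray
    tr_seconds: float
    icn_ids: tuple[int, ...] = ()
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x N), got shape {data.shape}")
        T, N = data.shape
        if N < 2:
            raise ValueError(f"need at least 2 ICNs, got {N}")
        if T < 2:
            raise ValueError(f"need at least 2 timepoints, got {T}")
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at timepoint {bad[0]}, column {bad[1]}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        ids = tuple(self.icn_ids) if self.icn_ids else tuple(range(1, N + 1))
        if len(ids) != N:
            raise ValueError(f"icn_ids has length {len(ids)}, expected {N}")
        if len(set(ids)) != N:
            raise ValueError("icn_ids must be unique")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "icn_ids", ids)
        object.__setattr__(self, "flags", frozenset(self.flags))
        unknown = self.flags - set(PREPROCESSING_FLAGS)
        if unknown:
            raise ValueError(f"unknown preprocessing flags: {sorted(unknown)}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_icn(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds

    def with_data(self, data: np.ndarray, add_flags: Iterable[str] = ()) -> "ICNTimeSeries":
        """Return a copy carrying new ``data`` and any additional flags."""
        return replace(self, data=data, flags=self.flags | frozenset(add_flags))
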