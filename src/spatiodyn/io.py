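"""File I/O: TSV time series with sidecar metadata, atlas tables,
templates, and cohort scan-time accounting.

All tabular artifacts are TSV for diffability. ICN ids are 1-based in
every file; timepoint indices are 0-based in occurrence files (stated in
their headers).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .atlas import AtlasMap
from .qpp import QPPTemplate
from .timeseries import ICNTimeSeries


class ParseError(ValueError):
    pass


def save_timeseries(ts: ICNTimeSeries, path, *, seed: int | None = None) -> None:
    """Write as TSV (header ``t`` + ICN ids, one row per timepoint) with a
    JSON sidecar carrying TR, preprocessing flags and the seed."""
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=[str(i) for i in ts.icn_ids])
    df.insert(0, "t", np.arange(ts.n_timepoints))
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"tr_seconds": ts.tr_seconds, "flags": sorted(ts.flags),
               "seed": seed, "n_timepoints": ts.n_timepoints,
               "n_icn": ts.n_icn}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n")


def load_timeseries(path, tr_seconds: float | None = None) -> ICNTimeSeries:
    """Read a time-series TSV; the sidecar supplies TR and flags when
    ``tr_seconds`` is not given."""
    path = Path(path)
    with open(path) as fh:
        widths = {ln: line.count("\t") for ln, line in enumerate(fh)
                  if line.strip()}
    if len(set(widths.values())) > 1:
        bad = next(ln for ln, w in widths.items() if w != widths[0])
        raise ParseError(f"{path}: row {bad} has a different number of "
                         "columns than the header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.columns[0] == "t":
        df = df.drop(columns="t")
    try:
        ids = tuple(int(c) for c in df.columns)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer ICN id in header") from exc
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate ICN ids in header")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        col = df.columns[df.isna().iloc[row].values.argmax()]
        raise ParseError(f"{path}: missing/NaN value at row {row}, ICN {col}")
    flags: list[str] = []
    if tr_seconds is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ParseError(f"{path}: no tr_seconds given and no sidecar "
                             f"{sidecar.name}")
        meta = json.loads(sidecar.read_text())
        tr_seconds = float(meta["tr_seconds"])
        flags = meta.get("flags", [])
    return ICNTimeSeries(data=df.to_numpy(dtype=float), tr_seconds=tr_seconds,
                         icn_ids=ids, flags=frozenset(flags))


def save_atlas(atlas: AtlasMap, path) -> None:
    rows = [{"icn_id": icn, "subdomain": sd,
             "domain": atlas.subdomain_to_domain[sd]}
            for icn, sd in sorted(atlas.icn_to_subdomain.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_atlas(path) -> AtlasMap:
    """Read an atlas TSV (columns icn_id, subdomain, domain)."""
    df = pd.read_csv(path, sep="\t")
    required = {"icn_id", "subdomain", "domain"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: atlas needs columns {sorted(required)}")
    if df["icn_id"].duplicated().any():
        dups = df.loc[df["icn_id"].duplicated(), "icn_id"].tolist()
        raise ParseError(f"{path}: duplicate ICN id(s) {dups}")
    sub_to_dom: dict[str, str] = {}
    for _, row in df.iterrows():
        sd, dom = str(row["subdomain"]), str(row["domain"])
        if sub_to_dom.setdefault(sd, dom) != dom:
            raise ParseError(f"{path}: subdomain {sd} mapped to both "
                             f"{sub_to_dom[sd]} and {dom}")
    icn_to_sub = {int(r["icn_id"]): str(r["subdomain"])
                  for _, r in df.iterrows()}
    return AtlasMap(icn_to_subdomain=icn_to_sub,
                    subdomain_to_domain=sub_to_dom)


def save_template(pattern: np.ndarray, path, icn_ids=None) -> None:
    """Template TSV: rows = ICNs (1-based ids), columns = window frames."""
    N, W = np.asarray(pattern).shape
    ids = list(icn_ids) if icn_ids else list(range(1, N + 1))
    df = pd.DataFrame(pattern, columns=[f"frame_{w}" for w in range(W)])
    df.insert(0, "icn_id", ids)
    df.to_csv(path, sep="\t", index=False)


def load_template(path) -> tuple[np.ndarray, tuple[int, ...]]:
    df = pd.read_csv(path, sep="\t")
    ids = tuple(int(i) for i in df["icn_id"])
    return df.drop(columns="icn_id").to_numpy(dtype=float), ids


def save_qpp(template: QPPTemplate, directory, prefix: str = "qpp") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_template(template.pattern, directory / f"{prefix}_template.tsv",
                  template.icn_ids)
    pd.DataFrame({"corr": template.corr_trace}).to_csv(
        directory / f"{prefix}_corr_trace.tsv", sep="\t", index=False)
    pd.DataFrame({"occurrence_start_0based": list(template.occurrences)}
                 ).to_csv(directory / f"{prefix}_occurrences.tsv", sep="\t",
                          index=False)


@dataclasses.dataclass(frozen=True)
class CohortManifest:
    """Cohort accounting: subject/session counts and total TR count.

    Scan hours are always derived (timepoints x TR / 3600), never stored.
    """

    label: str
    n_subjects: int
    n_sessions: int
    timepoints_total: int
    tr_seconds: float

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "timepoints_total"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


class ScanHours(NamedTuple):
    hours: float          # full precision
    hours_rounded: float  # as reported, 2 decimals


def cohort_scan_hours(manifest: CohortManifest) -> ScanHours:
    """Total scan time in hours from TR count: ``timepoints * TR / 3600``."""
    hours = manifest.timepoints_total * manifest.tr_seconds / 3600.0
    return ScanHours(hours=hours, hours_rounded=round(hours, 2))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
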