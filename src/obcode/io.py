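"""Session and result file formats plus run configuration.

A session directory contains ``session.json`` (metadata), ``traces.csv``
(long format: cell_id, odor_id, trial, frame, fluorescence) and an optional
``background.csv`` (frame, fluorescence).  Numbers are serialized with 17
significant digits so that read(write(x)) reproduces the float64 payload
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traces import ImagingSession

__all__ = ["write_session", "read_session", "RunConfig"]

log = logging.getLogger("obcode")

_FLOAT_FMT = "%.17g"
_TRACE_COLUMNS = ["cell_id", "odor_id", "trial", "frame", "fluorescence"]


def write_session(session: ImagingSession, path: str | Path) -> Path:
    """Write a session directory (session.json + traces.csv [+ background])."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "frame_rate": session.frame_rate,
        "onset_frame": session.onset_frame,
        "stim_s": session.stim_s,
        "cell_ids": list(session.cell_ids),
        "odor_ids": list(session.odor_ids),
        "n_trials": session.n_trials,
        "n_frames": session.n_frames,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    n_c, n_o, n_t, n_f = session.fluorescence.shape
    idx = pd.MultiIndex.from_product(
        [session.cell_ids, session.odor_ids, range(n_t), range(n_f)],
        names=_TRACE_COLUMNS[:4],
    )
    df = pd.DataFrame({"fluorescence": session.fluorescence.ravel()}, index=idx)
    df.reset_index().to_csv(path / "traces.csv", index=False, float_format=_FLOAT_FMT)
    if session.background is not None:
        pd.DataFrame(
            {"frame": np.arange(len(session.background)),
             "fluorescence": session.background}
        ).to_csv(path / "background.csv", index=False, float_format=_FLOAT_FMT)
    return path


def read_session(path: str | Path) -> ImagingSession:
    """Read and validate a session directory into a dense tensor."""
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    df = pd.read_csv(
        path / "traces.csv",
        dtype={"cell_id": str, "odor_id": str},
        float_precision="round_trip",
    )
    extra = [c for c in df.columns if c not in _TRACE_COLUMNS]
    if extra:
        log.warning("ignoring unknown columns in traces.csv: %s", extra)
        df = df[_TRACE_COLUMNS]
    missing_cols = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"traces.csv lacks required columns: {missing_cols}")
    dupes = df.duplicated(subset=_TRACE_COLUMNS[:4])
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValueError(
            "duplicate trace rows, first at "
            f"(cell={row.cell_id}, odor={row.odor_id}, trial={row.trial}, "
            f"frame={row.frame})"
        )
    cell_ids = [str(c) for c in meta["cell_ids"]]
    odor_ids = [str(o) for o in meta["odor_ids"]]
    n_t, n_f = int(meta["n_trials"]), int(meta["n_frames"])
    expected = pd.MultiIndex.from_product(
        [cell_ids, odor_ids, range(n_t), range(n_f)], names=_TRACE_COLUMNS[:4]
    )
    table = df.set_index(_TRACE_COLUMNS[:4])["fluorescence"]
    try:
        tensor = table.reindex(expected)
    except Exception as exc:  # unsortable/foreign keys
        raise ValueError(f"traces.csv index mismatch: {exc}") from exc
    if tensor.isna().any():
        tup = tensor[tensor.isna()].index[0]
        raise ValueError(
            f"traces.csv is missing (cell={tup[0]}, odor={tup[1]}, "
            f"trial={tup[2]}, frame={tup[3]})"
        )
    if len(df) != len(expected):
        raise ValueError(
            f"traces.csv has {len(df)} rows; expected {len(expected)} "
            "(ragged or surplus frames)"
        )
    background = None
    bg_path = path / "background.csv"
    if bg_path.exists():
        background = pd.read_csv(
            bg_path, float_precision="round_trip"
        )["fluorescence"].to_numpy()
    return ImagingSession(
        fluorescence=tensor.to_numpy().reshape(
            len(cell_ids), len(odor_ids), n_t, n_f
        ),
        frame_rate=float(meta["frame_rate"]),
        onset_frame=int(meta["onset_frame"]),
        condition=meta.get("condition", ""),
        subject_id=meta.get("subject_id", ""),
        cell_ids=tuple(cell_ids),
        odor_ids=tuple(odor_ids),
        stim_s=float(meta.get("stim_s", 2.0)),
        background=background,
    )


@dataclass
class RunConfig:
    """Tunable analysis windows, thresholds and stage selection for a run.

    Windows are (start, end) in seconds relative to odor onset.
    """

    stages: list[str] = field(
        default_factory=lambda: ["synth", "analyze", "dprime", "model", "iso"]
    )
    f0_window: tuple[float, float] = (-5.0, -2.0)
    response_window: tuple[float, float] = (0.0, 4.0)
    baseline_window: tuple[float, float] = (-6.0, -2.0)
    magnitude_window: tuple[float, float] = (0.0, 5.0)
    permutation_window: tuple[float, float] | None = None  # defaults to response
    es_threshold: float = 5.0
    alpha: float = 0.05
    smooth_span: int = 5
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    model: dict = field(default_factory=dict)  # NetworkParams overrides
    outdir: str = "obcode_run"

    def __post_init__(self) -> None:
        if self.es_threshold <= 0 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must be positive (alpha in (0, 1))")
        for name in ("f0_window", "response_window", "baseline_window",
                     "magnitude_window", "permutation_window"):
            w = getattr(self, name)
            if w is not None:
                setattr(self, name, tuple(float(x) for x in w))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable digest of the full configuration for the run manifest."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
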