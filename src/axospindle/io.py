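"""Reading and writing recordings, channel maps and event tables.

On-disk formats are deliberately simple and self-describing:

* **Recording** — a raw little-endian float32 channel-major matrix
  (``.f32``/``.raw``) plus a JSON sidecar with ``rate_hz``, ``channel_ids``,
  ``scale_uv`` (multiplier taking stored counts to microvolts) and ``t0_s``;
  alternatively a single HDF5 file with a ``data`` dataset carrying the same
  metadata as attributes.
* **ChannelMap** — a JSON document with ``electrodes`` and ``tunnels`` records.
* **EventTable** — plain CSV with a header, one row per event, times in
  seconds.

All timestamps everywhere in the package are seconds (float), sample indices
are 0-based, and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical feed-forward order of the reconstituted hippocampal loop
COMPARTMENT_LOOP = ("EC", "DG", "CA3", "CA1")

#: default spacing between the two electrodes of a microfluidic tunnel (um)
DEFAULT_TUNNEL_SPACING_UM = 200.0


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


class ValidationError(ValueError):
    """Raised when loaded data violates a structural invariant."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel extracellular voltage recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    rate_hz : float
        Sampling rate; 25000 for raw tunnel data, 1000 for the LFP.
    channel_ids : list of str
        Ordered electrode identifiers, one per data row.
    t0_s : float
        Time of sample 0 in seconds.
    """

    data: np.ndarray
    rate_hz: float
    channel_ids: list[str]
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds: ``t = t0_s + i / rate_hz``."""
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(channel_id)]


# ---------------------------------------------------------------------------
# Channel map
# ---------------------------------------------------------------------------

@dataclass
class Electrode:
    id: str
    x_um: float
    y_um: float
    compartment: str  # EC | DG | CA3 | CA1 | tunnel


@dataclass
class Tunnel:
    """A microfluidic tunnel holding two recording electrodes.

    ``upstream``/``downstream`` follow the feed-forward orientation
    EC -> DG -> CA3 -> CA1 -> EC, i.e. the upstream electrode sits on the
    ``source_compartment`` side.
    """

    tunnel_id: str
    source_compartment: str
    target_compartment: str
    upstream_electrode_id: str
    downstream_electrode_id: str
    electrode_spacing_um: float = DEFAULT_TUNNEL_SPACING_UM

    @property
    def spacing_mm(self) -> float:
        return self.electrode_spacing_um / 1000.0


@dataclass
class ChannelMap:
    electrodes: list[Electrode]
    tunnels: list[Tunnel]
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate electrode ids in channel map")
        self._by_id = {e.id: e for e in self.electrodes}
        valid = set(COMPARTMENT_LOOP) | {"tunnel"}
        for e in self.electrodes:
            if e.compartment not in valid:
                raise ValidationError(
                    f"electrode {e.id}: unknown compartment {e.compartment!r}"
                )
        for t in self.tunnels:
            for eid in (t.upstream_electrode_id, t.downstream_electrode_id):
                if eid not in self._by_id:
                    raise ValidationError(
                        f"tunnel {t.tunnel_id} references unknown electrode {eid}"
                    )
            if t.upstream_electrode_id == t.downstream_electrode_id:
                raise ValidationError(
                    f"tunnel {t.tunnel_id} must reference two distinct electrodes"
                )
            if t.electrode_spacing_um <= 0:
                raise ValidationError(
                    f"tunnel {t.tunnel_id}: electrode spacing must be positive"
                )

    def electrode(self, electrode_id: str) -> Electrode:
        return self._by_id[electrode_id]

    def tunnel(self, tunnel_id: str) -> Tunnel:
        for t in self.tunnels:
            if t.tunnel_id == tunnel_id:
                return t
        raise KeyError(tunnel_id)

    def tunnel_between(self, source: str, target: str) -> tuple[str, str, float]:
        """Electrode pair ``(first, second, spacing_um)`` for a directed query.

        A feed-forward query (source matches the tunnel's source compartment)
        returns ``(upstream, downstream)``; the feedback query for the same
        tunnel returns the flipped pair.  Flipping twice is the identity.
        """
        for t in self.tunnels:
            if (t.source_compartment, t.target_compartment) == (source, target):
                return (t.upstream_electrode_id, t.downstream_electrode_id,
                        t.electrode_spacing_um)
            if (t.target_compartment, t.source_compartment) == (source, target):
                return (t.downstream_electrode_id, t.upstream_electrode_id,
                        t.electrode_spacing_um)
        raise KeyError((source, target))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_recording(signal_path: str | Path, meta_path: str | Path | None = None
                   ) -> Recording:
    """Load a recording from raw float32 + JSON sidecar, or from HDF5.

    The sidecar must provide ``rate_hz`` and ``channel_ids``; ``scale_uv``
    (default 1.0) converts stored values to microvolts and ``t0_s`` defaults
    to 0.

    Raises
    ------
    FormatError
        If the file size is not a whole number of samples for the declared
        channel count.
    ValidationError
        If any sample is non-finite (the offending channels are listed).
    """
    signal_path = Path(signal_path)
    if signal_path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(signal_path, "r") as f:
            dset = f["data"]
            data = np.asarray(dset, dtype=np.float64)
            rate_hz = float(dset.attrs["rate_hz"])
            channel_ids = [str(c) for c in dset.attrs["channel_ids"]]
            scale = float(dset.attrs.get("scale_uv", 1.0))
            t0_s = float(dset.attrs.get("t0_s", 0.0))
    else:
        if meta_path is None:
            raise FormatError("raw float32 signal requires a JSON sidecar")
        meta = json.loads(Path(meta_path).read_text())
        rate_hz = float(meta["rate_hz"])
        channel_ids = [str(c) for c in meta["channel_ids"]]
        scale = float(meta.get("scale_uv", 1.0))
        t0_s = float(meta.get("t0_s", 0.0))
        n_ch = len(channel_ids)
        raw = np.fromfile(signal_path, dtype="<f4")
        n_bytes = signal_path.stat().st_size
        if n_bytes % 4 != 0:
            raise FormatError(
                f"{signal_path}: truncated mid-sample at byte {n_bytes}"
            )
        if raw.size % n_ch != 0:
            raise FormatError(
                f"{signal_path}: {raw.size} samples do not divide into "
                f"{n_ch} channels (file ends at byte {n_bytes})"
            )
        data = raw.reshape(n_ch, raw.size // n_ch).astype(np.float64)

    data = data * scale
    bad = [channel_ids[i] for i in range(data.shape[0])
           if not np.all(np.isfinite(data[i]))]
    if bad:
        raise ValidationError(f"non-finite samples on channels: {bad}")
    return Recording(data=data, rate_hz=rate_hz, channel_ids=channel_ids,
                     t0_s=t0_s)


def save_recording(rec: Recording, signal_path: str | Path,
                   meta_path: str | Path | None = None) -> None:
    """Write a recording as raw float32 + JSON sidecar, or HDF5 (.h5)."""
    signal_path = Path(signal_path)
    if signal_path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(signal_path, "w") as f:
            dset = f.create_dataset("data", data=rec.data.astype("<f4"))
            dset.attrs["rate_hz"] = rec.rate_hz
            dset.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
            dset.attrs["scale_uv"] = 1.0
            dset.attrs["t0_s"] = rec.t0_s
        return
    if meta_path is None:
        raise ValueError("raw float32 output requires a sidecar path")
    rec.data.astype("<f4").tofile(signal_path)
    Path(meta_path).write_text(json.dumps({
        "rate_hz": rec.rate_hz,
        "channel_ids": list(rec.channel_ids),
        "scale_uv": 1.0,
        "t0_s": rec.t0_s,
        "units": "uV",
    }, indent=2))


def load_channel_map(path: str | Path) -> ChannelMap:
    """Load and validate a JSON channel map."""
    doc = json.loads(Path(path).read_text())
    electrodes = [Electrode(id=str(e["id"]), x_um=float(e.get("x_um", 0.0)),
                            y_um=float(e.get("y_um", 0.0)),
                            compartment=str(e["compartment"]))
                  for e in doc.get("electrodes", [])]
    tunnels = []
    for t in doc.get("tunnels", []):
        if "electrode_spacing_um" not in t:
            log.info("tunnel %s: electrode_spacing_um missing, using default "
                     "%g um", t.get("tunnel_id"), DEFAULT_TUNNEL_SPACING_UM)
        tunnels.append(Tunnel(
            tunnel_id=str(t["tunnel_id"]),
            source_compartment=str(t["source_compartment"]),
            target_compartment=str(t["target_compartment"]),
            upstream_electrode_id=str(t["upstream_electrode_id"]),
            downstream_electrode_id=str(t["downstream_electrode_id"]),
            electrode_spacing_um=float(t.get("electrode_spacing_um",
                                             DEFAULT_TUNNEL_SPACING_UM)),
        ))
    return ChannelMap(electrodes=electrodes, tunnels=tunnels)


def save_channel_map(cmap: ChannelMap, path: str | Path) -> None:
    doc = {
        "electrodes": [vars(e) for e in cmap.electrodes],
        "tunnels": [{k: v for k, v in vars(t).items()} for t in cmap.tunnels],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

#: columns every event table starts with; event-type payload columns follow
EVENT_CORE_COLUMNS = ["channel_id", "event_type", "start_s", "end_s"]


def make_event_table(rows: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Validate and sort an event table (sorted by start within channel)."""
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=EVENT_CORE_COLUMNS)
    missing = [c for c in EVENT_CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    if (df["end_s"] < df["start_s"]).any():
        raise ValidationError("event with end_s < start_s")
    return df.sort_values(["channel_id", "start_s"], kind="stable"
                          ).reset_index(drop=True)


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as CSV; times keep sub-millisecond precision."""
    df = table.copy()
    for c in df.columns:
        if df[c].dtype.kind == "f":
            df[c] = df[c].round(6)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        return df
    return make_event_table(df)
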