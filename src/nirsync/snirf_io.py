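"""SNIRF (HDF5) read/write for dyadic recordings.

Implements the SNIRF 1.0 layout directly with h5py: one `/nirs` block per
file with a continuous-wave amplitude data element (channels x wavelengths
flattened into measurement-list entries), probe geometry with optode labels,
and one stim group per event label.  Montage ROI assignments, which SNIRF
has no native slot for, ride along in ``metaDataTags`` as a JSON string so
the round trip is lossless.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .montage import Channel, Montage, Optode
from .simulate import Event, RawRecording


class SnirfParseError(ValueError):
    """Malformed SNIRF file; message includes the offending element path."""


def _write_str(group, name, value: str):
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(recording: RawRecording, path) -> None:
    """Write one subject's recording to a SNIRF 1.0 file."""
    m = recording.montage
    n_ch = recording.n_channels
    n_wl = len(recording.wavelengths_nm)
    nt = recording.n_times

    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")

        meta = nirs.create_group("metaDataTags")
        _write_str(meta, "SubjectID", recording.subject_id)
        _write_str(meta, "MeasurementDate", "unknown")
        _write_str(meta, "MeasurementTime", "unknown")
        _write_str(meta, "LengthUnit", "cm")
        _write_str(meta, "TimeUnit", "s")
        _write_str(meta, "FrequencyUnit", "Hz")
        montage_json = json.dumps(
            {
                "sources": [[o.label, o.x, o.y] for o in m.sources],
                "detectors": [[o.label, o.x, o.y] for o in m.detectors],
                "channels": [
                    [c.index, c.source, c.detector, c.distance_cm, c.roi]
                    for c in m.channels
                ],
                "anchor_labels": m.anchor_labels,
            }
        )
        _write_str(meta, "nirsyncMontage", montage_json)

        data = nirs.create_group("data1")
        # measurements ordered channel-major, wavelength-minor
        flat = recording.intensity.reshape(n_ch * n_wl, nt).T
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(nt) / recording.fs_hz)
        src_labels = [o.label for o in m.sources]
        det_labels = [o.label for o in m.detectors]
        k = 1
        for c in m.channels:
            for wi in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=src_labels.index(c.source) + 1)
                ml.create_dataset("detectorIndex", data=det_labels.index(c.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)        # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(recording.wavelengths_nm, float))
        spos = np.array([[o.x, o.y] for o in m.sources])
        dpos = np.array([[o.x, o.y] for o in m.detectors])
        probe.create_dataset("sourcePos2D", data=spos)
        probe.create_dataset("detectorPos2D", data=dpos)
        probe.create_dataset("sourcePos3D", data=np.c_[spos, np.zeros(len(spos))])
        probe.create_dataset("detectorPos3D", data=np.c_[dpos, np.zeros(len(dpos))])
        probe.create_dataset(
            "sourceLabels", data=np.array([np.bytes_(s) for s in src_labels])
        )
        probe.create_dataset(
            "detectorLabels", data=np.array([np.bytes_(s) for s in det_labels])
        )

        by_label: dict[str, list[Event]] = {}
        for ev in recording.events:
            by_label.setdefault(ev.label, []).append(ev)
        for i, (label, evs) in enumerate(sorted(by_label.items()), start=1):
            stim = nirs.create_group(f"stim{i}")
            _write_str(stim, "name", label)
            stim.create_dataset(
                "data",
                data=np.array([[e.onset_s, e.duration_s, 1.0] for e in evs]),
            )


def _require(f, path):
    if path not in f:
        raise SnirfParseError(f"missing required element {path!r}")
    return f[path]


def read_snirf(path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` back to a recording."""
    with h5py.File(path, "r") as f:
        _require(f, "formatVersion")
        nirs = _require(f, "nirs")
        probe = _require(f, "nirs/probe")
        if "wavelengths" not in probe:
            raise SnirfParseError("missing required element 'nirs/probe/wavelengths'")
        wavelengths = tuple(int(round(w)) for w in probe["wavelengths"][()])

        meta = _require(f, "nirs/metaDataTags")
        subject = meta["SubjectID"][()].decode() if "SubjectID" in meta else "unknown"
        if "nirsyncMontage" in meta:
            mj = json.loads(meta["nirsyncMontage"][()].decode())
            montage = Montage(
                sources=[Optode(l, x, y) for l, x, y in mj["sources"]],
                detectors=[Optode(l, x, y) for l, x, y in mj["detectors"]],
                channels=[Channel(i, s, d, dist, roi) for i, s, d, dist, roi in mj["channels"]],
                anchor_labels=mj["anchor_labels"],
            )
        else:
            raise SnirfParseError("missing montage sidecar 'nirs/metaDataTags/nirsyncMontage'")

        data = _require(f, "nirs/data1")
        ts = _require(f, "nirs/data1/dataTimeSeries")[()]
        time = _require(f, "nirs/data1/time")[()]
        if len(time) < 2:
            raise SnirfParseError("'nirs/data1/time' must hold the full time vector")
        fs = 1.0 / float(time[1] - time[0])

        n_wl = len(wavelengths)
        n_meas = ts.shape[1]
        if n_meas % n_wl:
            raise SnirfParseError("measurement count is not a multiple of wavelengths")
        n_ch = n_meas // n_wl
        # verify wavelength indices follow the channel-major layout we write
        for k in range(1, n_meas + 1):
            ml = _require(f, f"nirs/data1/measurementList{k}")
            wi = int(ml["wavelengthIndex"][()])
            if wi != (k - 1) % n_wl + 1:
                raise SnirfParseError(
                    f"unexpected wavelengthIndex at nirs/data1/measurementList{k}"
                )
        intensity = ts.T.reshape(n_ch, n_wl, ts.shape[0])

        events = []
        for name in sorted(nirs.keys()):
            if name.startswith("stim"):
                stim = nirs[name]
                label = stim["name"][()].decode()
                for onset, dur, _ in np.atleast_2d(stim["data"][()]):
                    events.append(Event(float(onset), float(dur), label))
        events.sort(key=lambda e: e.onset_s)

    rec = RawRecording(
        subject_id=subject,
        montage=montage,
        intensity=intensity,
        fs_hz=fs,
        events=events,
        wavelengths_nm=wavelengths,
    )
    rec.validate()
    return rec
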