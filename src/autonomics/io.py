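"""Session and result I/O: one delimited numeric file per channel plus a
JSON manifest, and truth/feature/stats serialization."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .synthetic import Session, SyntheticTruth, PhaseParams

__all__ = ["write_session", "read_session", "write_truth", "read_truth"]


def _dump_json(obj, path):
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def write_session(directory, session, truth=None):
    """Write one channel file per modality plus ``manifest.json`` (and the
    generating truth when given)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, x in (("ecg", session.ecg), ("resp", session.resp),
                    ("eda", session.eda)):
        np.savetxt(d / f"{name}.csv", x, fmt="%.6g")
    manifest = {
        "subject_id": session.subject_id,
        "group": session.group,
        "fs": {"ecg": session.fs_ecg, "resp": session.fs_resp,
               "eda": session.fs_eda},
        "phase_bounds": {k: list(v) for k, v in session.phase_bounds.items()},
        "suds": session.suds,
        "cortisol": list(session.cortisol),
    }
    _dump_json(manifest, d / "manifest.json")
    if truth is not None:
        write_truth(d / "truth.json", truth)
    return d


def read_session(directory):
    """Load a session written by :func:`write_session`."""
    d = Path(directory)
    man = json.loads((d / "manifest.json").read_text())
    chans = {name: np.loadtxt(d / f"{name}.csv") for name in ("ecg", "resp", "eda")}
    return Session(
        subject_id=man["subject_id"], group=man["group"],
        ecg=chans["ecg"], resp=chans["resp"], eda=chans["eda"],
        fs_ecg=float(man["fs"]["ecg"]), fs_resp=float(man["fs"]["resp"]),
        fs_eda=float(man["fs"]["eda"]),
        phase_bounds={k: tuple(v) for k, v in man["phase_bounds"].items()},
        suds=man["suds"], cortisol=tuple(man["cortisol"]),
    )


def write_truth(path, truth):
    """Serialize the generating parameters (not the bulky realizations)."""
    obj = {
        "subject_id": truth.subject_id, "group": truth.group,
        "phases": {k: dataclasses.asdict(v) for k, v in truth.phases.items()},
        "suds": truth.suds, "cortisol": list(truth.cortisol),
        "seed": truth.seed, "coupling_lag": truth.coupling_lag,
        "ar_pole_modulus": truth.ar_pole_modulus,
        "ar_pole_freq": truth.ar_pole_freq,
        "tonic_slope": truth.tonic_slope,
        "scr_events": {k: [list(e) for e in v] for k, v in truth.scr_events.items()},
        "coherent_fraction": truth.coherent_fraction,
    }
    _dump_json(obj, path)


def read_truth(path):
    obj = json.loads(Path(path).read_text())
    truth = SyntheticTruth(
        subject_id=obj["subject_id"], group=obj["group"],
        phases={k: PhaseParams(**v) for k, v in obj["phases"].items()},
        suds=obj["suds"], cortisol=tuple(obj["cortisol"]), seed=obj["seed"],
        coupling_lag=obj["coupling_lag"],
        ar_pole_modulus=obj["ar_pole_modulus"],
        ar_pole_freq=obj["ar_pole_freq"], tonic_slope=obj["tonic_slope"],
    )
    truth.scr_events = {k: [tuple(e) for e in v] for k, v in obj["scr_events"].items()}
    truth.coherent_fraction = obj["coherent_fraction"]
    return truth
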