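"""Trial and study-bundle persistence.

Text-first formats: one wide CSV per trial with segment-prefixed pose columns
(``t, <seg>_q_w, <seg>_q_x, <seg>_q_y, <seg>_q_z, <seg>_p_x, ...``), one CSV
per measured IMU sensor (``t, ax, ay, az, gx, gy, gz``), per-trial angle and
moment CSVs, and a ``study.json`` manifest carrying rate, subject metadata,
gait events, the placement library and a config hash.  Placement-augmented
IMU trials are regenerated from the library on load rather than stored.

An optional single-file HDF5 container mirrors the same hierarchy for
network-ready tensors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DatasetTensors
from .rigid import SEGMENTS, IMUSignal, PoseSequence, SensorPlacement
from .syngait import CHANNELS, GaitTrial, StudyBundle, SubjectSpec


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-trial CSVs


def trial_poses_frame(trial: GaitTrial) -> pd.DataFrame:
    n = len(next(iter(trial.segment_poses.values())))
    data = {"t": np.arange(n) / trial.rate}
    for seg in SEGMENTS:
        pose = trial.segment_poses[seg]
        for k, name in enumerate(("q_w", "q_x", "q_y", "q_z")):
            data[f"{seg}_{name}"] = pose.orientations[:, k]
        for k, name in enumerate(("p_x", "p_y", "p_z")):
            data[f"{seg}_{name}"] = pose.origins[:, k]
    return pd.DataFrame(data)


def poses_from_frame(df: pd.DataFrame, rate: float) -> dict[str, PoseSequence]:
    out = {}
    for seg in SEGMENTS:
        q = df[[f"{seg}_q_{c}" for c in "wxyz"]].to_numpy()
        p = df[[f"{seg}_p_{c}" for c in "xyz"]].to_numpy()
        out[seg] = PoseSequence(rate=rate, orientations=q, origins=p)
    return out


def imu_frame(sig: IMUSignal) -> pd.DataFrame:
    n = len(sig)
    return pd.DataFrame(
        {
            "t": np.arange(n) / sig.rate,
            "ax": sig.accel[:, 0], "ay": sig.accel[:, 1], "az": sig.accel[:, 2],
            "gx": sig.gyro[:, 0], "gy": sig.gyro[:, 1], "gz": sig.gyro[:, 2],
        }
    )


def imu_from_frame(df: pd.DataFrame, rate: float) -> IMUSignal:
    return IMUSignal(
        rate=rate,
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )


def _placement_dict(p: SensorPlacement) -> dict:
    return {
        "segment_id": p.segment_id,
        "offset_t": p.offset_t.tolist(),
        "offset_q": p.offset_q.tolist(),
    }


def _placement_from(d: dict) -> SensorPlacement:
    return SensorPlacement(d["segment_id"], np.array(d["offset_t"]),
                           np.array(d["offset_q"]))


# ---------------------------------------------------------------------------
# study bundle


def save_bundle(bundle: StudyBundle, out_dir: str | Path,
                config: dict | None = None, force: bool = False) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "subjects": [],
        "trials": [],
        "placement_library": {
            sid: {seg: _placement_dict(p) for seg, p in pset.items()}
            for sid, pset in bundle.placement_library.items()
        },
        "channels": list(CHANNELS),
    }
    for s in bundle.cohort:
        manifest["subjects"].append(
            {
                "subject_id": s.subject_id,
                "mass": s.mass,
                "height": s.height,
                "segment_lengths": s.segment_lengths,
                "gait_coeffs": {k: v.tolist() for k, v in s.gait_coeffs.items()},
                "has_ground_truth_sensors": s.has_ground_truth_sensors,
                "placements": {seg: _placement_dict(p)
                               for seg, p in s.placements.items()},
                "seed": s.seed,
            }
        )
    for i, trial in enumerate(bundle.trials):
        stem = f"trial_{i:04d}"
        trial_poses_frame(trial).to_csv(out / f"{stem}_poses.csv", index=False)
        pd.DataFrame(trial.joint_angles.T, columns=CHANNELS).to_csv(
            out / f"{stem}_angles.csv", index=False)
        pd.DataFrame(trial.joint_moments.T, columns=CHANNELS).to_csv(
            out / f"{stem}_moments.csv", index=False)
        measured = []
        key = (trial.subject_id, i)
        if key in bundle.measured_imu:
            for seg, sig in bundle.measured_imu[key].items():
                fname = f"{stem}_imu_{seg}.csv"
                imu_frame(sig).to_csv(out / fname, index=False)
                measured.append(seg)
        manifest["trials"].append(
            {
                "index": i,
                "subject_id": trial.subject_id,
                "speed": trial.speed,
                "rate": trial.rate,
                "events": trial.events,
                "measured_segments": measured,
            }
        )
    (out / "study.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_bundle(bundle_dir: str | Path, regenerate_augmented: bool = True
                ) -> StudyBundle:
    from .rigid import augment

    root = Path(bundle_dir)
    manifest = json.loads((root / "study.json").read_text())
    cohort = [
        SubjectSpec(
            subject_id=s["subject_id"],
            mass=s["mass"],
            height=s["height"],
            segment_lengths=s["segment_lengths"],
            gait_coeffs={k: np.array(v) for k, v in s["gait_coeffs"].items()},
            has_ground_truth_sensors=s["has_ground_truth_sensors"],
            placements={seg: _placement_from(p)
                        for seg, p in s["placements"].items()},
            seed=s["seed"],
        )
        for s in manifest["subjects"]
    ]
    library = {
        sid: {seg: _placement_from(p) for seg, p in pset.items()}
        for sid, pset in manifest["placement_library"].items()
    }
    trials = []
    measured: dict[tuple[str, int], dict[str, IMUSignal]] = {}
    for t in manifest["trials"]:
        i = t["index"]
        stem = f"trial_{i:04d}"
        poses = poses_from_frame(pd.read_csv(root / f"{stem}_poses.csv"),
                                 t["rate"])
        angles = pd.read_csv(root / f"{stem}_angles.csv").to_numpy().T
        moments = pd.read_csv(root / f"{stem}_moments.csv").to_numpy().T
        trials.append(
            GaitTrial(
                subject_id=t["subject_id"],
                speed=t["speed"],
                rate=t["rate"],
                joint_angles=angles,
                joint_moments=moments,
                events=t["events"],
                segment_poses=poses,
            )
        )
        if t["measured_segments"]:
            measured[(t["subject_id"], i)] = {
                seg: imu_from_frame(
                    pd.read_csv(root / f"{stem}_imu_{seg}.csv"), t["rate"])
                for seg in t["measured_segments"]
            }
    augmented = []
    if regenerate_augmented and library:
        for ti, trial in enumerate(trials):
            sims = augment(trial.segment_poses, list(library.values()))
            for sid, imu in zip(library.keys(), sims):
                augmented.append(
                    {"trial_index": ti, "placement_subject": sid, "imu": imu}
                )
    return StudyBundle(cohort=cohort, trials=trials, measured_imu=measured,
                       augmented=augmented, placement_library=library)


# ---------------------------------------------------------------------------
# tensor container (HDF5)


def save_tensors_h5(t: DatasetTensors, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["layout"] = t.layout
        f.create_dataset("X", data=t.X)
        f.create_dataset("Y", data=t.Y)
        idx = np.array([f"{a}|{b}|{c}" for a, b, c in t.sample_index], dtype="S")
        f.create_dataset("sample_index", data=idx)
        for name, scaler in (("x_scaler", t.x_scaler), ("y_scaler", t.y_scaler)):
            if scaler is not None:
                grp = f.create_group(name)
                grp.attrs["kind"] = scaler.kind
                grp.create_dataset("center", data=scaler.center)
                grp.create_dataset("scale", data=scaler.scale)


def load_tensors_h5(path: str | Path) -> DatasetTensors:
    import h5py

    from .preprocess import Scaler

    with h5py.File(path, "r") as f:
        scalers = {}
        for name in ("x_scaler", "y_scaler"):
            if name in f:
                s = Scaler(f[name].attrs["kind"])
                s.center = f[name]["center"][...]
                s.scale = f[name]["scale"][...]
                scalers[name] = s
        index = [tuple(x.decode().split("|")) for x in f["sample_index"][...]]
        return DatasetTensors(
            layout=f.attrs["layout"],
            X=f["X"][...],
            Y=f["Y"][...],
            sample_index=[(a, int(b), c) for a, b, c in index],
            x_scaler=scalers.get("x_scaler"),
            y_scaler=scalers.get("y_scaler"),
        )
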