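"""Readers and writers: IDX image files, session logs, stimulus sets.

Sessions are stored as JSON Lines — one session object per line, class
sets serialised as sorted arrays, a leading ``#`` comment line carrying
provenance — so logs are streamable and diff-able. Stimulus sets are a
directory of per-class NPY stacks plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .stimuli import ClassTemplate, RawImage, Stimulus, class_means
from .task_env import Episode, Session

SESSIONS_SCHEMA_ID = "glimpsekit/sessions/v1"


class DataError(ValueError):
    """A file failed to parse or validate."""


# ---------------------------------------------------------------------------
# IDX (MNIST/EMNIST-style) files

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def read_idx_images(path: str | Path) -> np.ndarray:
    """Read an idx3-ubyte image file into an (N, rows, cols) array in [0, 1]."""
    data = Path(path).read_bytes()
    if len(data) < 16:
        raise DataError(f"{path}: truncated header at byte {len(data)} (need 16)")
    magic, n, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise DataError(
            f"{path}: bad magic 0x{magic:08x} at byte 0 (expected 0x{_IDX_IMAGES_MAGIC:08x})"
        )
    expected = 16 + n * rows * cols
    if len(data) != expected:
        raise DataError(
            f"{path}: expected {expected} bytes, file ends at byte {len(data)}"
        )
    pixels = np.frombuffer(data, dtype=np.uint8, offset=16).reshape(n, rows, cols)
    return pixels.astype(float) / 255.0


def read_idx_labels(path: str | Path) -> np.ndarray:
    """Read an idx1-ubyte label file into an (N,) integer array."""
    data = Path(path).read_bytes()
    if len(data) < 8:
        raise DataError(f"{path}: truncated header at byte {len(data)} (need 8)")
    magic, n = struct.unpack(">II", data[:8])
    if magic != _IDX_LABELS_MAGIC:
        raise DataError(
            f"{path}: bad magic 0x{magic:08x} at byte 0 (expected 0x{_IDX_LABELS_MAGIC:08x})"
        )
    if len(data) != 8 + n:
        raise DataError(f"{path}: expected {8 + n} bytes, file ends at byte {len(data)}")
    return np.frombuffer(data, dtype=np.uint8, offset=8).astype(int)


def read_idx(images_path: str | Path, labels_path: str | Path | None = None) -> list[RawImage]:
    """Load an IDX image file (optionally with labels) as RawImage objects."""
    images = read_idx_images(images_path)
    if labels_path is not None:
        labels = read_idx_labels(labels_path)
        if len(labels) != len(images):
            raise DataError(
                f"{labels_path}: {len(labels)} labels for {len(images)} images"
            )
    else:
        labels = np.zeros(len(images), dtype=int)
    return [RawImage(pixels=img, label=int(lbl)) for img, lbl in zip(images, labels)]


# ---------------------------------------------------------------------------
# provenance

def provenance_block(config: dict, seed: int | None = None) -> dict:
    """Reproducibility stamp: config hash, seed and package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "version": __version__,
    }


# ---------------------------------------------------------------------------
# session logs (JSON Lines)


def _session_to_dict(session: Session) -> dict:
    return {
        "schema_id": SESSIONS_SCHEMA_ID,
        "stimulus_id": session.stimulus_id,
        "dataset_tag": session.dataset_tag,
        "true_class": session.true_class,
        "episodes": [
            {
                "t": e.t,
                "row": e.row,
                "col": e.col,
                "classes": sorted(e.classes),
                "duration_s": round(float(e.duration_s), 6),
            }
            for e in session.episodes
        ],
        "scores": [round(float(s), 10) for s in session.scores],
        "h": round(float(session.h), 10),
    }


def write_sessions(
    sessions: Sequence[Session],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    path = Path(path)
    header = {"schema_id": SESSIONS_SCHEMA_ID, **(provenance or {})}
    with path.open("w") as fh:
        fh.write(f"# glimpsekit sessions {json.dumps(header, sort_keys=True)}\n")
        for s in sessions:
            fh.write(json.dumps(_session_to_dict(s), sort_keys=True) + "\n")


def _require(obj: dict, key: str, lineno: int):
    if key not in obj:
        raise DataError(f"line {lineno}: missing field '{key}'")
    return obj[key]


def read_sessions(path: str | Path) -> list[Session]:
    """Read and validate a JSON Lines session log.

    Raises :class:`DataError` naming the offending line and field.
    """
    sessions: list[Session] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DataError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict):
                raise DataError(f"line {lineno}: expected an object")
            if _require(obj, "schema_id", lineno) != SESSIONS_SCHEMA_ID:
                raise DataError(
                    f"line {lineno}: field 'schema_id' is {obj['schema_id']!r}, "
                    f"expected {SESSIONS_SCHEMA_ID!r}"
                )
            episodes = []
            raw_eps = _require(obj, "episodes", lineno)
            if not isinstance(raw_eps, list):
                raise DataError(f"line {lineno}: field 'episodes' must be an array")
            for e in raw_eps:
                for key in ("t", "row", "col", "classes"):
                    _require(e, key, lineno)
                if not e["classes"]:
                    raise DataError(f"line {lineno}: field 'classes' must be non-empty")
                episodes.append(
                    Episode(
                        t=int(e["t"]),
                        row=int(e["row"]),
                        col=int(e["col"]),
                        classes=frozenset(int(c) for c in e["classes"]),
                        duration_s=float(e.get("duration_s", 0.0)),
                    )
                )
            sessions.append(
                Session(
                    stimulus_id=str(_require(obj, "stimulus_id", lineno)),
                    dataset_tag=str(_require(obj, "dataset_tag", lineno)),
                    true_class=int(_require(obj, "true_class", lineno)),
                    episodes=episodes,
                    scores=[float(s) for s in _require(obj, "scores", lineno)],
                    h=float(_require(obj, "h", lineno)),
                )
            )
    return sessions


# ---------------------------------------------------------------------------
# saliency sets


def save_saliency_set(sal, path: str | Path) -> None:
    """Serialise a SaliencySet to a single NPZ archive.

    The archive holds one array per ordered class pair (key ``"D_i_j"``)
    plus a JSON manifest with theta and the smoothing parameters.
    """
    manifest = {
        "format": "glimpsekit/saliency/v1",
        "theta": sal.theta,
        "mode": sal.mode,
        "sigma": sal.sigma,
        "kernel_size": sal.kernel_size,
        "delta": sal.delta,
        "pairs": [[i, j] for i, j in sorted(sal.maps)],
    }
    arrays = {f"D_{i}_{j}": m for (i, j), m in sal.maps.items()}
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)


def load_saliency_set(path: str | Path):
    """Read a SaliencySet archive written by :func:`save_saliency_set`."""
    from .baseline import SaliencySet

    with np.load(path) as archive:
        if "manifest" not in archive:
            raise DataError(f"{path}: not a saliency archive (no manifest)")
        manifest = json.loads(archive["manifest"].tobytes().decode())
        if manifest.get("format") != "glimpsekit/saliency/v1":
            raise DataError(f"{path}: unknown format {manifest.get('format')!r}")
        maps = {
            (int(i), int(j)): archive[f"D_{i}_{j}"] for i, j in manifest["pairs"]
        }
    return SaliencySet(
        maps=maps,
        theta=float(manifest["theta"]),
        mode=manifest["mode"],
        sigma=float(manifest["sigma"]),
        kernel_size=int(manifest["kernel_size"]),
        delta=float(manifest["delta"]),
    )


# ---------------------------------------------------------------------------
# stimulus sets


def save_stimulus_set(
    stimuli: Sequence[Stimulus],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write per-class NPY stacks plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_class: dict[int, list[Stimulus]] = {}
    for s in stimuli:
        by_class.setdefault(s.class_id, []).append(s)
    manifest = {
        "format": "glimpsekit/stimuli/v1",
        "dataset_tag": stimuli[0].dataset_tag if stimuli else "synthetic",
        "classes": sorted(by_class),
        "counts": {str(c): len(v) for c, v in sorted(by_class.items())},
        "provenance": provenance or {},
    }
    for cid, items in by_class.items():
        np.save(out / f"class_{cid:03d}.npy", np.stack([s.pixels for s in items]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_stimulus_set(
    in_dir: str | Path,
) -> tuple[list[Stimulus], list[ClassTemplate]]:
    """Read a stimulus-set directory back; templates are recomputed."""
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"{src}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "glimpsekit/stimuli/v1":
        raise DataError(f"{manifest_path}: unknown format {manifest.get('format')!r}")
    tag = manifest.get("dataset_tag", "synthetic")
    stimuli: list[Stimulus] = []
    for cid in manifest["classes"]:
        stack = np.load(src / f"class_{int(cid):03d}.npy")
        for pixels in stack:
            stimuli.append(Stimulus(pixels=pixels, class_id=int(cid), dataset_tag=tag))
    templates = class_means(stimuli, max(int(c) for c in manifest["classes"]))
    return stimuli, templates
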