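"""Minimal extended-XYZ reader/writer for particle snapshots.

Frames carry a comment line of ``key=value`` pairs (``Lattice``,
``Properties``, plus free metadata) and one whitespace-delimited row per
particle.  Only the fields this package emits are supported: species tag,
position, and optionally velocity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["write_frames", "read_frames"]


def _format_comment(box: tuple[float, float, float], time: float,
                    has_velocity: bool, extra: dict | None) -> str:
    lx, ly, lz = box
    props = "species:S:1:pos:R:3" + (":vel:R:3" if has_velocity else "")
    fields = {
        "Lattice": f'"{lx:g} 0 0 0 {ly:g} 0 0 0 {lz:g}"',
        "Properties": props,
        "Time": f"{time:.10g}",
    }
    if extra:
        for k, v in extra.items():
            fields[k] = f"{v:g}" if isinstance(v, float) else str(v)
    return " ".join(f"{k}={v}" for k, v in fields.items())


def write_frames(
    path: str | Path,
    frames: list[np.ndarray],
    species: np.ndarray | list[str],
    box: tuple[float, float, float],
    times: np.ndarray | None = None,
    velocities: list[np.ndarray] | None = None,
    extra: dict | None = None,
    mode: str = "w",
) -> Path:
    """Write a multi-frame extended-XYZ file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    species = [str(s) for s in species]
    if times is None:
        times = np.arange(len(frames), dtype=float)
    with open(path, mode) as fh:
        for k, frame in enumerate(frames):
            frame = np.asarray(frame)
            vel = None if velocities is None else np.asarray(velocities[k])
            fh.write(f"{len(frame)}\n")
            fh.write(_format_comment(box, float(times[k]), vel is not None, extra))
            fh.write("\n")
            for idx in range(len(frame)):
                x, y, z = frame[idx]
                line = f"{species[idx]} {x:.9g} {y:.9g} {z:.9g}"
                if vel is not None:
                    vx, vy, vz = vel[idx]
                    line += f" {vx:.9g} {vy:.9g} {vz:.9g}"
                fh.write(line + "\n")
    return path


def _parse_comment(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    i = 0
    while i < len(line):
        eq = line.find("=", i)
        if eq < 0:
            break
        key = line[i:eq].strip().split()[-1]
        rest = line[eq + 1 :]
        if rest.startswith('"'):
            end = rest.find('"', 1)
            val = rest[1:end]
            i = eq + 2 + end
        else:
            sp = rest.find(" ")
            if sp < 0:
                val, i = rest, len(line)
            else:
                val, i = rest[:sp], eq + 2 + sp
        out[key] = val
    return out


def read_frames(path: str | Path) -> Iterator[dict]:
    """Yield frames as dicts with keys species, positions, velocities, meta."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            meta = _parse_comment(fh.readline().strip())
            species, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
            arr = np.array(rows)
            yield {
                "species": species,
                "positions": arr[:, :3],
                "velocities": arr[:, 3:6] if arr.shape[1] >= 6 else None,
                "meta": meta,
            }
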