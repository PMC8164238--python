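"""Versioned plain-text serialization of tuned models.

The format is a self-describing tab-separated text file: a header line
naming the format version, key/value lines for the kernel, C, bias, Platt
parameters, posterior weight and the feature recipe, an optional PSSM
block, and one line per training point carrying λ, y and the feature
coordinates.  Floats are written with `repr`, which round-trips exactly
in Python 3, so load(save(m)) reproduces the model bit for bit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .errors import AcpsmoError
from .features import FeatureSpec, Pssm
from .model_selection import TunedModel
from .smo import KernelSpec, SvmModel

_MAGIC = "#acpsmo-model v1"


def _fmt(x: Optional[float]) -> str:
    return "-" if x is None else repr(float(x))


def _parse(s: str) -> Optional[float]:
    return None if s == "-" else float(s)


def save_model(path, tuned: TunedModel, spec: FeatureSpec) -> Path:
    """Write a tuned model (and its feature recipe) as versioned text."""
    path = Path(path)
    m = tuned.base
    lines = [
        _MAGIC,
        f"kernel\t{m.kernel.kind}",
        f"gamma\t{_fmt(m.kernel.gamma)}",
        f"C\t{_fmt(m.C)}",
        f"bias\t{_fmt(m.bias)}",
        f"platt_a\t{_fmt(m.platt_a)}",
        f"platt_b\t{_fmt(m.platt_b)}",
        f"weight\t{_fmt(tuned.weight)}",
        f"dual_objective\t{_fmt(m.dual_objective)}",
        f"feature_spec\t{spec.fingerprint()}",
        f"encoders\t{','.join(spec.encoders)}",
        f"k_values\t{','.join(str(k) for k in spec.k_values) or '-'}",
        f"n5c5_mode\t{spec.n5c5_mode}",
        f"n_points\t{len(m.x)}",
        f"n_dims\t{m.x.shape[1]}",
    ]
    if spec.pssm is not None:
        p = spec.pssm
        lines.append(f"pssm\t{p.n_positions}\t{_fmt(p.pseudocount)}\t{p.source_n}")
        lines.append("pssm_background\t" + ",".join(repr(float(v)) for v in p.background))
        for row in p.matrix:
            lines.append("pssm_row\t" + ",".join(repr(float(v)) for v in row))
    else:
        lines.append("pssm\t-")
    for lam, y, row in zip(m.lambdas, m.y, m.x):
        lines.append(
            f"point\t{repr(float(lam))}\t{int(y)}\t" + ",".join(repr(float(v)) for v in row)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_model(path) -> tuple[TunedModel, FeatureSpec]:
    """Read a model file written by :func:`save_model` (exact round-trip)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise AcpsmoError(f"{path}: not an acpsmo model file (missing '{_MAGIC}' header)")
    kv: dict[str, str] = {}
    pssm_rows: list[list[float]] = []
    pssm_bg: Optional[np.ndarray] = None
    pssm_meta: Optional[tuple[int, float, int]] = None
    points: list[tuple[float, int, np.ndarray]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        key = fields[0]
        if key == "point":
            lam = float(fields[1])
            y = int(fields[2])
            row = np.array([float(v) for v in fields[3].split(",")])
            points.append((lam, y, row))
        elif key == "pssm" and fields[1] != "-":
            pssm_meta = (int(fields[1]), float(fields[2]), int(fields[3]))
        elif key == "pssm_background":
            pssm_bg = np.array([float(v) for v in fields[1].split(",")])
        elif key == "pssm_row":
            pssm_rows.append([float(v) for v in fields[1].split(",")])
        else:
            kv[key] = fields[1] if len(fields) > 1 else ""

    kernel = KernelSpec(kv["kernel"], _parse(kv["gamma"]))
    pssm = None
    if pssm_meta is not None:
        pssm = Pssm(
            matrix=np.array(pssm_rows),
            background=pssm_bg,
            pseudocount=pssm_meta[1],
            source_n=pssm_meta[2],
        )
    k_values = tuple(int(k) for k in kv["k_values"].split(",")) if kv["k_values"] != "-" else ()
    spec = FeatureSpec(
        encoders=tuple(kv["encoders"].split(",")),
        k_values=k_values,
        pssm=pssm,
        n5c5_mode=kv["n5c5_mode"],
    )
    lambdas = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points], dtype=float)
    X = np.vstack([p[2] for p in points])
    model = SvmModel(
        x=X,
        y=y,
        lambdas=lambdas,
        bias=_parse(kv["bias"]),
        kernel=kernel,
        C=_parse(kv["C"]),
        w=None,
        platt_a=_parse(kv["platt_a"]),
        platt_b=_parse(kv["platt_b"]),
        dual_objective=_parse(kv["dual_objective"]) or 0.0,
        feature_fingerprint=kv["feature_spec"],
    )
    if kernel.kind == "linear":
        model.w = (lambdas * y) @ X
    return TunedModel(base=model, weight=_parse(kv["weight"])), spec
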