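"""Versioned plain-text serialization for models (exact round-trip).

Format: a header line, ``key: value`` scalars, and named arrays written
with full ``repr`` precision (one row per line), so load(save(m)) is
bit-identical.
"""

from __future__ import annotations

import os

import numpy as np

from .alphabet import RNA
from .hpm import HiddenPottsModel
from .phmm import ProfileHMM
from .potts import PottsModel

MAGIC = "# hpmtools model v1"


def _write_array(fh, name: str, arr: np.ndarray) -> None:
    fh.write(f"array {name} {' '.join(map(str, arr.shape))}\n")
    flat = arr.reshape(-1, arr.shape[-1]) if arr.ndim > 1 else arr.reshape(1, -1)
    for row in flat:
        fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _save(path, kind: str, scalars: dict, arrays: dict) -> None:
    with open(path, "w") as fh:
        fh.write(MAGIC + "\n")
        fh.write(f"kind: {kind}\n")
        for k, v in scalars.items():
            fh.write(f"{k}: {v}\n")
        for name, arr in arrays.items():
            _write_array(fh, name, np.asarray(arr, dtype=float))


def _load(path) -> tuple[str, dict, dict]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != MAGIC:
        raise ValueError(f"{path}: not an hpmtools v1 model file")
    scalars: dict = {}
    arrays: dict = {}
    i = 1
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("array "):
            _, name, *shape = ln.split()
            shape = tuple(int(s) for s in shape)
            nrows = int(np.prod(shape[:-1])) if len(shape) > 1 else 1
            vals = []
            for j in range(nrows):
                vals.append([float(v) for v in lines[i + 1 + j].split()])
            arrays[name] = np.array(vals).reshape(shape)
            i += 1 + nrows
        else:
            k, _, v = ln.partition(": ")
            scalars[k] = v
            i += 1
    return scalars.pop("kind"), scalars, arrays


def save_phmm(hmm: ProfileHMM, path: str | os.PathLike) -> None:
    _save(path, "phmm", {"M": hmm.M},
          {"tm": hmm.tm, "ti": hmm.ti, "td": hmm.td,
           "e_match": hmm.e_match, "e_insert": hmm.e_insert,
           "background": hmm.background})


def load_phmm(path: str | os.PathLike) -> ProfileHMM:
    kind, scalars, arr = _load(path)
    if kind != "phmm":
        raise ValueError(f"expected phmm model, found {kind}")
    return ProfileHMM(M=int(scalars["M"]), alphabet=RNA, **arr)


def save_potts(potts: PottsModel, path: str | os.PathLike) -> None:
    _save(path, "potts", {"M": potts.M, "K": potts.K},
          {"h": potts.h, "e": potts.e})


def load_potts(path: str | os.PathLike) -> PottsModel:
    kind, _, arr = _load(path)
    if kind != "potts":
        raise ValueError(f"expected potts model, found {kind}")
    return PottsModel(h=arr["h"], e=arr["e"])


def save_hpm(hpm: HiddenPottsModel, path: str | os.PathLike) -> None:
    _save(path, "hpm", {"M": hpm.M},
          {"h": hpm.potts.h, "e": hpm.potts.e,
           "t_open": hpm.t_open, "t_ext": hpm.t_ext,
           "e_insert": hpm.e_insert, "background": hpm.background})


def load_hpm(path: str | os.PathLike) -> HiddenPottsModel:
    kind, _, arr = _load(path)
    if kind != "hpm":
        raise ValueError(f"expected hpm model, found {kind}")
    potts = PottsModel(h=arr["h"], e=arr["e"])
    return HiddenPottsModel(potts=potts, t_open=arr["t_open"],
                            t_ext=arr["t_ext"], e_insert=arr["e_insert"],
                            background=arr["background"])
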