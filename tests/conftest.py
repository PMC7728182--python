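"""Shared fixtures: tiny enumerable models and a small synthetic family."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hpmtools.hpm import HiddenPottsModel
from hpmtools.phmm import PHMMPath, ProfileHMM
from hpmtools.potts import PottsModel


def toy_phmm(M: int = 3) -> ProfileHMM:
    """Small hand-set profile HMM with all transitions possible."""
    tm = np.array([[0.7, 0.2, 0.1]] * M + [[0.8, 0.2, 0.0]])
    ti = np.array([[0.6, 0.3, 0.1]] * M + [[0.7, 0.3, 0.0]])
    td = np.array([[0.0, 0.0, 0.0]] + [[0.6, 0.15, 0.25]] * (M - 1)
                  + [[0.8, 0.2, 0.0]])
    base = np.array([
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.7, 0.1, 0.1],
        [0.1, 0.1, 0.7, 0.1],
        [0.1, 0.1, 0.1, 0.7],
    ])
    em = base[np.arange(M) % 4]
    return ProfileHMM(M=M, tm=tm, ti=ti, td=td, e_match=em,
                      e_insert=np.full(4, 0.25), background=np.full(4, 0.25))


def random_potts(M: int = 3, scale: float = 0.4, seed: int = 7) -> PottsModel:
    rng = np.random.default_rng(seed)
    h = rng.normal(0, scale, (M, 5))
    e = rng.normal(0, scale, (M, M, 5, 5))
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    e[np.arange(M), np.arange(M)] = 0.0
    return PottsModel(h=h, e=e)


def toy_hpm(M: int = 3, seed: int = 7) -> HiddenPottsModel:
    potts = random_potts(M, seed=seed)
    t_open = np.linspace(0.1, 0.25, M + 1)
    t_ext = np.full(M + 1, 0.35)
    return HiddenPottsModel(potts=potts, t_open=t_open, t_ext=t_ext,
                            e_insert=np.array([0.3, 0.2, 0.25, 0.25]),
                            background=np.full(4, 0.25))


def enumerate_glocal_paths(M: int, L: int):
    """All glocal pHMM paths for a length-L sequence (tiny M, L only)."""
    for d in range(M + 1):
        n_ins = L - (M - d)
        if n_ins < 0:
            continue
        for dels in itertools.combinations(range(1, M + 1), d):
            for bars in itertools.combinations(range(n_ins + M), M):
                counts = []
                prev = -1
                for b in bars:
                    counts.append(b - prev - 1)
                    prev = b
                counts.append(n_ins + M - 1 - prev)
                states: list[tuple[str, int]] = []
                for k in range(M + 1):
                    if k > 0:
                        states.append(("D" if k in dels else "M", k))
                    states += [("I", k)] * counts[k]
                yield PHMMPath(states=states)


@pytest.fixture(scope="session")
def phmm3() -> ProfileHMM:
    return toy_phmm(3)


@pytest.fixture(scope="session")
def hpm3() -> HiddenPottsModel:
    return toy_hpm(3)


@pytest.fixture(scope="session")
def small_family():
    """A small conserved synthetic family (shared across tests)."""
    from hpmtools.synthetic import synthetic_family

    return synthetic_family("twister-like", n_seqs=80, seed=3, burn_in=1000)
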