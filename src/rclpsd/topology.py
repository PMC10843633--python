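"""Chain connectivity: backbone, random cross-links and binding sites.

A cross-link realization is a fixed set of harmonic springs between randomly
chosen, non-adjacent monomer pairs; the set is drawn once per realization and
kept static for the whole run (quenched disorder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Topology:
    """Connectivity of one polymer + molecules system.

    Backbone bonds are implicit between consecutive monomers ``(i, i+1)``.
    ``cross_links`` holds unordered pairs ``(i, j)`` with ``|i - j| >= 2``;
    ``binding_sites`` are monomer indices carrying the attractive well.
    """

    n_mon: int
    n_mol: int = 0
    cross_links: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    binding_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.cross_links = np.asarray(self.cross_links, dtype=np.int64).reshape(-1, 2)
        self.binding_sites = np.asarray(self.binding_sites, dtype=np.int64).reshape(-1)
        if self.n_mon < 1 or self.n_mol < 0:
            raise ValueError("need n_mon >= 1 and n_mol >= 0")
        cl = self.cross_links
        if cl.size:
            cl = np.sort(cl, axis=1)
            if np.any(cl[:, 0] == cl[:, 1]):
                raise ValueError("cross-link joins a monomer to itself")
            if np.any(np.abs(cl[:, 0] - cl[:, 1]) < 2):
                raise ValueError("cross-link duplicates a backbone bond")
            if cl.min() < 0 or cl.max() >= self.n_mon:
                raise ValueError("cross-link index out of range")
            if len({tuple(p) for p in cl.tolist()}) != len(cl):
                raise ValueError("duplicate cross-links")
            self.cross_links = cl
        if self.binding_sites.size:
            if self.binding_sites.min() < 0 or self.binding_sites.max() >= self.n_mon:
                raise ValueError("binding-site index out of range")
            if len(set(self.binding_sites.tolist())) != len(self.binding_sites):
                raise ValueError("duplicate binding sites")

    @property
    def n_c(self) -> int:
        return len(self.cross_links)

    @property
    def n_bs(self) -> int:
        return len(self.binding_sites)

    @property
    def n_particles(self) -> int:
        return self.n_mon + self.n_mol

    def species(self) -> np.ndarray:
        """Per-particle labels: 'S' binding-site monomer, 'M' monomer, 'B' molecule."""
        lab = np.array(["M"] * self.n_mon + ["B"] * self.n_mol, dtype="U1")
        lab[self.binding_sites] = "S"
        return lab

    # --- plain-text serialization (lossless round trip) -------------------

    def write(self, path: str | Path) -> None:
        lines = [
            f"n_mon {self.n_mon}",
            f"n_mol {self.n_mol}",
            f"n_crosslinks {self.n_c}",
            f"n_binding_sites {self.n_bs}",
        ]
        lines += [f"crosslink {i} {j}" for i, j in self.cross_links]
        lines += [f"binding_site {s}" for s in self.binding_sites]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Topology":
        head: dict[str, int] = {}
        links: list[tuple[int, int]] = []
        sites: list[int] = []
        for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
            tok = raw.split()
            if not tok:
                continue
            if tok[0] == "crosslink":
                links.append((int(tok[1]), int(tok[2])))
            elif tok[0] == "binding_site":
                sites.append(int(tok[1]))
            elif tok[0] in ("n_mon", "n_mol", "n_crosslinks", "n_binding_sites"):
                head[tok[0]] = int(tok[1])
            else:
                raise ValueError(f"unrecognized topology record on line {ln}: {raw!r}")
        if len(links) != head.get("n_crosslinks", 0) or len(sites) != head.get("n_binding_sites", 0):
            raise ValueError("topology header counts disagree with records")
        return cls(
            n_mon=head["n_mon"],
            n_mol=head.get("n_mol", 0),
            cross_links=np.array(links, dtype=np.int64).reshape(-1, 2),
            binding_sites=np.array(sites, dtype=np.int64),
        )


def admissible_pairs(n_mon: int) -> list[tuple[int, int]]:
    """All unordered monomer pairs (i, j) with j - i >= 2."""
    return [(i, j) for i in range(n_mon) for j in range(i + 2, n_mon)]


def sample_crosslinks(n_mon: int, n_c: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n_c`` distinct cross-link pairs uniformly without replacement.

    Admissible pairs exclude identical and backbone-adjacent monomers
    (``|i - j| >= 2``).  Deterministic for a fixed seed/Generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pairs = admissible_pairs(n_mon)
    if n_c > len(pairs):
        raise ValueError(f"requested {n_c} cross-links but only {len(pairs)} admissible pairs")
    if n_c == 0:
        return np.empty((0, 2), dtype=np.int64)
    idx = rng.choice(len(pairs), size=n_c, replace=False)
    out = np.array([pairs[k] for k in sorted(idx)], dtype=np.int64)
    return out


def make_topology(
    n_mon: int,
    n_mol: int = 0,
    n_c: int = 0,
    n_bs: int = 0,
    rng: np.random.Generator | int = 0,
) -> Topology:
    """Random realization: uniform cross-links plus uniformly drawn binding sites."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    links = sample_crosslinks(n_mon, n_c, rng)
    sites = (
        np.sort(rng.choice(n_mon, size=n_bs, replace=False)).astype(np.int64)
        if n_bs
        else np.empty(0, dtype=np.int64)
    )
    return Topology(n_mon=n_mon, n_mol=n_mol, cross_links=links, binding_sites=sites)
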