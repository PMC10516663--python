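"""Nearest-neighbor free-energy evaluation of RNA secondary structures.

Scores a *given* sequence + base-pair set at 37 C with Turner-style
nearest-neighbor tables (packaged 1999 vintage): helix stacks, hairpin
loops (initiation + terminal mismatch + tetraloop bonuses), bulges,
generic internal loops and an affine multiloop term.  Pseudoknotted pair
sets are decomposed into non-crossing layers which are scored
independently and summed, with no junction penalty — sufficient for the
relative ranking of descriptor matches, and exact for pseudoknot-free
hairpins such as the T7-leader stem used as a worked example.

Not modeled: coaxial stacking, dangling ends, exterior-loop terms,
special small internal-loop lookup tables, temperature dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .seqio import StructureValidityError, layer_pairs

CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def pair_kind(a: str, b: str) -> str | None:
    """'WC', 'GU' or None for a putative base pair."""
    if (a, b) in WOBBLE:
        return "GU"
    if (a, b) in CANONICAL:
        return "WC"
    return None


@dataclass(frozen=True)
class EnergyModel:
    """Parsed nearest-neighbor tables (kcal/mol at 37 C)."""

    stack: dict[tuple[str, str], float]
    hairpin_init: dict[int, float]
    tstackh: dict[tuple[str, str, str], float]
    tetraloop: dict[str, float]
    bulge_init: dict[int, float]
    internal_init: dict[int, float]
    terminal_au: float
    internal_au: float
    bulge_au: float
    lxc: float
    ninio_m: float
    ninio_max: float
    multi_close: float
    multi_branch: float
    multi_unpaired: float

    def loop_extrapolate(self, table: dict[int, float], n: int) -> float:
        cap = max(table)
        if n <= cap:
            return table[n]
        return table[cap] + self.lxc * math.log(n / cap)


@dataclass(frozen=True)
class EnergyBreakdown:
    total: float
    terms: tuple[tuple[str, float], ...]


def load_model(path=None) -> EnergyModel:
    """Load the packaged (or a user-supplied) parameter file."""
    if path is None:
        text = (resources.files("iresscope.data") / "turner1999_nn.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    section = None
    stack: dict[tuple[str, str], float] = {}
    hairpin: dict[int, float] = {}
    tstackh: dict[tuple[str, str, str], float] = {}
    tetra: dict[str, float] = {}
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    scalars: dict[str, list[float]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] in ("STACK", "HAIRPIN", "TSTACKH", "TETRALOOP", "BULGE", "INTERNAL"):
            section = parts[0]
            continue
        if parts[0] in ("TERMINAL_AU", "INTERNAL_AU", "BULGE_AU", "LXC",
                        "NINIO", "MULTI"):
            scalars[parts[0]] = [float(x) for x in parts[1:]]
            continue
        if section == "STACK":
            stack[(parts[0], parts[1])] = float(parts[2])
        elif section == "HAIRPIN":
            hairpin[int(parts[0])] = float(parts[1])
        elif section == "TSTACKH":
            tstackh[(parts[0], parts[1], parts[2])] = float(parts[3])
        elif section == "TETRALOOP":
            tetra[parts[0]] = float(parts[1])
        elif section == "BULGE":
            bulge[int(parts[0])] = float(parts[1])
        elif section == "INTERNAL":
            internal[int(parts[0])] = float(parts[1])
        else:
            raise ValueError(f"parameter line outside a section: {raw!r}")
    missing = {("STACK", 36, len(stack)), ("TSTACKH", 96, len(tstackh))}
    for name, want, got in missing:
        if got != want:
            raise ValueError(f"incomplete {name} table: {got}/{want} entries")
    return EnergyModel(
        stack=stack,
        hairpin_init=hairpin,
        tstackh=tstackh,
        tetraloop=tetra,
        bulge_init=bulge,
        internal_init=internal,
        terminal_au=scalars["TERMINAL_AU"][0],
        internal_au=scalars["INTERNAL_AU"][0],
        bulge_au=scalars["BULGE_AU"][0],
        lxc=scalars["LXC"][0],
        ninio_m=scalars["NINIO"][0],
        ninio_max=scalars["NINIO"][1],
        multi_close=scalars["MULTI"][0],
        multi_branch=scalars["MULTI"][1],
        multi_unpaired=scalars["MULTI"][2],
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_model()
    return _DEFAULT_MODEL


def _validate_pairs(seq: str, pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    seen: set[int] = set()
    norm = []
    for i, j in pairs:
        i, j = (i, j) if i < j else (j, i)
        if i == j:
            raise StructureValidityError(f"self-pair at {i}")
        if i in seen or j in seen:
            raise StructureValidityError(f"position in two pairs: ({i},{j})")
        seen.update((i, j))
        if not (0 <= i < j < len(seq)):
            raise StructureValidityError(f"pair ({i},{j}) outside sequence")
        if pair_kind(seq[i], seq[j]) is None:
            raise StructureValidityError(
                f"non-complementary pair {seq[i]}{i}-{seq[j]}{j}"
            )
        norm.append((i, j))
    return sorted(norm)


def _score_nested(seq: str, pairs: list[tuple[int, int]], model: EnergyModel,
                  terms: list[tuple[str, float]]) -> None:
    """Score one non-crossing pair layer; positions paired in other layers
    are treated as unpaired here (zero-penalty pseudoknot decomposition)."""
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stackp: list[tuple[int, int]] = []
    for p in pairs:  # sorted by opening position: enclosure via a stack
        while stackp and not (stackp[-1][0] < p[0] and p[1] < stackp[-1][1]):
            stackp.pop()
        (children[stackp[-1]] if stackp else roots).append(p)
        stackp.append(p)
    for (i, j), kids in children.items():
        cp = seq[i] + seq[j]
        if not kids:
            n = j - i - 1
            if n < 3:
                raise StructureValidityError(f"hairpin loop of {n} nt at ({i},{j})")
            e = model.loop_extrapolate(model.hairpin_init, n)
            label = f"hairpin({i + 1},{j + 1})"
            if n == 3 and cp not in ("CG", "GC"):
                e += model.terminal_au
            if n >= 4:
                e += model.tstackh[(cp, seq[i + 1], seq[j - 1])]
            if n == 4:
                e += model.tetraloop.get(seq[i : j + 1], 0.0)
            terms.append((label, round(e, 2)))
        elif len(kids) == 1:
            k, l = kids[0]
            top, bot = k - i - 1, j - l - 1
            kp = seq[k] + seq[l]
            if top == 0 and bot == 0:
                terms.append((f"stack({i + 1},{j + 1})", model.stack[(cp, kp)]))
            elif top == 0 or bot == 0:
                n = top + bot
                e = model.loop_extrapolate(model.bulge_init, n)
                if n == 1:
                    e += model.stack[(cp, kp)]
                else:
                    for pp in (cp, kp):
                        if pp not in ("CG", "GC"):
                            e += model.bulge_au
                terms.append((f"bulge({i + 1},{j + 1})", round(e, 2)))
            else:
                n = top + bot
                e = model.loop_extrapolate(model.internal_init, n)
                e += min(model.ninio_max, model.ninio_m * abs(top - bot))
                for pp in (cp, kp):
                    if pp not in ("CG", "GC"):
                        e += model.internal_au
                terms.append((f"internal({i + 1},{j + 1})", round(e, 2)))
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            e = (model.multi_close + model.multi_branch * (len(kids) + 1)
                 + model.multi_unpaired * unpaired)
            terms.append((f"multiloop({i + 1},{j + 1})", round(e, 2)))


def evaluate_structure(seq: str, pairs: Sequence[tuple[int, int]],
                       model: EnergyModel | None = None) -> EnergyBreakdown:
    """Itemized free energy of ``pairs`` (0-based) on ``seq``.

    Crossing pair sets are split into non-crossing layers (greedy, same
    rule as the dot-bracket writer) and each layer is scored as a nested
    structure; the layers' energies are summed.
    """
    model = model or default_model()
    norm = _validate_pairs(seq, pairs)
    terms: list[tuple[str, float]] = []
    if norm:
        for layer in layer_pairs(norm):
            _score_nested(seq, sorted(layer), model, terms)
    total = round(sum(v for _, v in terms), 2)
    return EnergyBreakdown(total=total, terms=tuple(terms))


def rank_matches(matches):
    """Stable sort of descriptor matches: score desc, then dG asc, then
    5'-most, then shortest."""
    return sorted(
        matches,
        key=lambda m: (-m.score, m.delta_g, m.genome_interval.start,
                       len(m.genome_interval)),
    )
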