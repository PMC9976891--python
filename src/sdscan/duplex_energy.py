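"""Register-wise rRNA:mRNA hybridization free energies.

The extended anti-Shine-Dalgarno (ASD) tail of 16S rRNA is slid, rigidly
and without gaps, along an mRNA window.  At each register the aligned
positions that form Watson-Crick or G·U pairs (antiparallel) are found,
maximal runs of consecutive pairs are enumerated, and each run of at least
two pairs is scored with the nearest-neighbor model:

    dG(run) = dG_init + sum(stack dG over the run) + terminal penalties

where the terminal penalty applies to each A·U or G·U pair closing the
helix.  A register's free energy is the best (most negative) run score,
capped at zero: a register with no stabilizing helix scores 0.  Only the
single best contiguous run is scored — no bulges, internal loops or
multi-helix sums — so energies are comparable only under this convention.

Stack parameters are the Turner 2004 RNA/RNA set (Watson-Crick stacks of
Xia et al. 1998, G·U stacks of Mathews et al. 1999) at 37 degrees C,
shipped as a versioned TSV resource.  N never pairs and contributes no
stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NNParameterTable",
    "RegisterScore",
    "pair_mask",
    "enumerate_runs",
    "score_run",
    "register_delta_g",
    "scan_registers",
]

# (ASD base, mRNA base) combinations that pair in antiparallel orientation.
PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
# Pairs that draw the terminal penalty when they close a helix.
_WEAK_PAIRS = frozenset([("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")])


@dataclass(frozen=True)
class NNParameterTable:
    """Immutable nearest-neighbor parameter set.

    ``stacks`` maps a key ``"x1x2/y1y2"`` — top strand 5'-x1 x2-3' over
    bottom strand 3'-y1 y2-5', with x1·y1 and x2·y2 paired — to the stack
    ΔG°37 in kcal/mol.
    """

    stacks: dict
    init: float
    terminal_au: float
    version: str

    @classmethod
    def from_tsv(cls, path) -> "NNParameterTable":
        stacks: dict = {}
        init = terminal = None
        version = "unversioned"
        for line in Path(path).read_text().splitlines():
            if line.startswith("# version:"):
                version = line.split(":", 1)[1].strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")
            if key == "init":
                init = float(value)
            elif key == "terminal_au":
                terminal = float(value)
            elif key.startswith("stack:"):
                stacks[key[len("stack:"):]] = float(value)
            else:
                raise ValueError(f"unknown parameter key {key!r}")
        if init is None or terminal is None or not stacks:
            raise ValueError(f"{path}: incomplete parameter table")
        return cls(stacks=stacks, init=init, terminal_au=terminal, version=version)

    @classmethod
    def default(cls) -> "NNParameterTable":
        ref = resources.files("sdscan").joinpath("data/nn_turner2004.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class RegisterScore:
    """Best helix at one register.

    ``offset`` identifies the register (the caller's register coordinate);
    ``dG`` ≤ 0 with dG = 0 meaning no stabilizing helix, in which case
    ``helix_len`` is reported as 0; ``helix_span`` gives the (low, high)
    mRNA coordinates of the scored helix, in the caller's coordinates.
    """

    offset: int
    dG: float
    helix_len: int
    helix_span: tuple | None


def pair_mask(asd: str, mrna_window: str, register: int) -> list:
    """Pairing mask of the ASD laid antiparallel on the window.

    ``register`` is the window index paired with the ASD 5' base; ASD base
    ``i`` is paired with window index ``register - i`` (the mRNA runs
    3'→5' under the ASD).  Positions falling outside the window, or
    opposite N, are unpaired.  Raises if no position overlaps the window.
    """
    n = len(mrna_window)
    if register < 0 or register - (len(asd) - 1) > n - 1:
        raise ValueError(
            f"register {register} gives zero overlap with window of length {n}"
        )
    mask = []
    for i, a in enumerate(asd):
        j = register - i
        mask.append(0 <= j < n and (a, mrna_window[j]) in PAIRS)
    return mask


def enumerate_runs(mask: Sequence) -> list:
    """Maximal runs of consecutive True values as (start, stop) half-open."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def score_run(
    asd: str, mrna_window: str, register: int, run: tuple, params: NNParameterTable
) -> float:
    """Nearest-neighbor ΔG of one run of consecutive pairs (kcal/mol)."""
    i0, i1 = run
    if i1 - i0 < 2:
        raise ValueError("a helix needs at least two base pairs")
    total = params.init
    for i in range(i0, i1 - 1):
        key = (
            asd[i]
            + asd[i + 1]
            + "/"
            + mrna_window[register - i]
            + mrna_window[register - i - 1]
        )
        total += params.stacks[key]
    for i in (i0, i1 - 1):
        if (asd[i], mrna_window[register - i]) in _WEAK_PAIRS:
            total += params.terminal_au
    return total


def register_delta_g(
    asd: str, mrna_window: str, register: int, params: NNParameterTable
) -> RegisterScore:
    """Score one register: the best stabilizing run, capped at zero."""
    mask = pair_mask(asd, mrna_window, register)
    best = 0.0
    best_run = None
    for run in enumerate_runs(mask):
        if run[1] - run[0] < 2:
            continue
        s = score_run(asd, mrna_window, register, run, params)
        if s < best:
            best, best_run = s, run
    if best_run is None:
        return RegisterScore(offset=register, dG=0.0, helix_len=0, helix_span=None)
    lo = register - (best_run[1] - 1)
    hi = register - best_run[0]
    return RegisterScore(
        offset=register, dG=best, helix_len=best_run[1] - best_run[0],
        helix_span=(lo, hi),
    )


def scan_registers(
    asd: str, tir, registers: Iterable, params: NNParameterTable
) -> list:
    """Scan a TIR over a set of registers.

    ``tir`` is any object with ``seq`` (RNA string) and ``start_index``
    (index of the first start-codon base).  A register ``o`` is the
    distance in nt between the ASD 5' end (16S nt 1532) and the first
    nucleotide of the start codon: the ASD 5' base sits at TIR offset
    ``-o``.  Registers with no overlap are reported as dG = 0.  Offsets
    and helix spans in the result are TIR coordinates (start codon = 0).
    """
    seq, s0 = tir.seq, tir.start_index
    out = []
    for o in sorted(registers):
        j0 = s0 - o
        if j0 < 0 or j0 - (len(asd) - 1) > len(seq) - 1:
            out.append(RegisterScore(offset=o, dG=0.0, helix_len=0, helix_span=None))
            continue
        rs = register_delta_g(asd, seq, j0, params)
        span = (
            None
            if rs.helix_span is None
            else (rs.helix_span[0] - s0, rs.helix_span[1] - s0)
        )
        out.append(
            RegisterScore(offset=o, dG=rs.dG, helix_len=rs.helix_len, helix_span=span)
        )
    return out
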