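"""Independent reference implementations used to cross-check the package.

These deliberately share no code with ``sdscan``: the alignment oracle is
a plain dynamic-programming matrix, and the energy oracle re-reads the
parameter TSV with its own parser and scores runs by naive string
walking.
"""

from __future__ import annotations

from pathlib import Path

_DATA = Path(__file__).resolve().parents[1] / "src" / "sdscan" / "data" / "nn_turner2004.tsv"

_COMPLEMENT_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}
_WEAK = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def load_raw_table() -> dict:
    stacks = {}
    init = terminal = None
    for line in _DATA.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        if key == "init":
            init = float(value)
        elif key == "terminal_au":
            terminal = float(value)
        else:
            stacks[key.removeprefix("stack:")] = float(value)
    return {"stacks": stacks, "init": init, "terminal": terminal}


# ---------------------------------------------------------------------------
# Semi-global alignment (full query coverage, free target ends)
# ---------------------------------------------------------------------------

def dp_semiglobal(query: str, target: str, max_errors: int):
    """Leftmost best end of an infix alignment of ``query`` in ``target``.

    Returns (n_errors, end_exclusive) or None if the best alignment has
    more than ``max_errors`` unit-cost errors.
    """
    m, n = len(query), len(target)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            sub = prev[j - 1] + (query[i - 1] != target[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    best = min(prev[1:])
    if best > max_errors:
        return None
    end = next(j for j in range(1, n + 1) if prev[j] == best)
    return best, end


# ---------------------------------------------------------------------------
# Brute-force register scanning
# ---------------------------------------------------------------------------

def _paired(a: str, b: str) -> bool:
    return (a, b) in _COMPLEMENT_PAIRS


def oracle_register_score(asd, seq, j0, table):
    """Best run score at one raw register (j0 = window index of ASD base 0)."""
    runs = []
    current = []
    for i in range(len(asd)):
        j = j0 - i
        if 0 <= j < len(seq) and _paired(asd[i], seq[j]):
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    best = 0.0
    best_run = None
    for run in runs:
        if len(run) < 2:
            continue
        total = table["init"]
        for i in run[:-1]:
            key = asd[i] + asd[i + 1] + "/" + seq[j0 - i] + seq[j0 - i - 1]
            total += table["stacks"][key]
        for i in (run[0], run[-1]):
            if (asd[i], seq[j0 - i]) in _WEAK:
                total += table["terminal"]
        if total < best:
            best, best_run = total, run
    return best, best_run


def oracle_scan(asd, seq, start_index, offsets, table):
    """dG per TIR register offset, mirroring the package's convention."""
    out = {}
    for o in offsets:
        j0 = start_index - o
        if j0 < 0 or j0 - (len(asd) - 1) > len(seq) - 1:
            out[o] = 0.0
            continue
        out[o] = oracle_register_score(asd, seq, j0, table)[0]
    return out


def oracle_window_min(asd, seq, start_index, lo, hi, table):
    """Minimum ΔG over maximal runs wholly inside TIR coords [lo, hi].

    Runs are found on the unrestricted pairing mask; a run with any base
    pair outside the window is skipped entirely (no truncation).
    """
    best = 0.0
    L = len(asd)
    for o in range(-hi - (L - 1), -lo + 1):
        j0 = start_index - o
        current = []
        runs = []
        for i in range(L):
            j = j0 - i
            if 0 <= j < len(seq) and _paired(asd[i], seq[j]):
                current.append(i)
            else:
                if current:
                    runs.append(current)
                current = []
        if current:
            runs.append(current)
        for run in runs:
            if len(run) < 2:
                continue
            coords = [-o - i for i in run]
            if min(coords) < lo or max(coords) > hi:
                continue
            total = table["init"]
            for i in run[:-1]:
                key = asd[i] + asd[i + 1] + "/" + seq[j0 - i] + seq[j0 - i - 1]
                total += table["stacks"][key]
            for i in (run[0], run[-1]):
                if (asd[i], seq[j0 - i]) in _WEAK:
                    total += table["terminal"]
            best = min(best, total)
    return best
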