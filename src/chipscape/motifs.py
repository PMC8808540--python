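"""PWM scanning and motif-enrichment logic over enhancer sequences.

Scanning: log-odds of a position weight matrix against a background base
composition, both strands, with a hit threshold expressed as a fraction of
the maximum achievable score.  Enrichment: one-sided hypergeometric test on
the number of sequences with >= 1 hit, foreground versus a
dinucleotide-shuffled background (2x the foreground count by default).
Selection logic on top (condition-differential motifs, cell-type-specific
TFs and their preservation under the MUT condition) uses raw p-value
thresholds; BH-adjusted q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_fdr

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_NEG_INF = -1e9


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold_fraction must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log-odds with probabilities floored at 1e-3."""
        p = np.maximum(self.matrix, 1e-3)
        return np.log(p / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background.copy(),
            threshold_fraction=self.threshold_fraction,
        )


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-style plain-text matrices.

    Format per motif: a ``>motif_id [name]`` header then four lines
    ``A [ 1 2 3 ... ]`` (counts or probabilities; columns are normalized).
    """
    pwms: list[PWM] = []
    current_id = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for ln in lines + [">__end__"]:
        if ln.startswith(">"):
            if current_id is not None:
                if set(rows) != set(_BASES):
                    raise ValueError(f"motif {current_id}: missing base rows")
                mat = np.asarray([rows[b] for b in _BASES], dtype=float)
                mat = mat / mat.sum(axis=0, keepdims=True)
                pwms.append(PWM(motif_id=current_id, matrix=mat))
            current_id = ln[1:].split()[0] if ln != ">__end__" else None
            rows = {}
        else:
            base = ln[0].upper()
            body = ln[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    return pwms


def write_jaspar(path, pwms: Sequence[PWM], counts_scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for bi, b in enumerate(_BASES):
                vals = " ".join(f"{v * counts_scale:.2f}" for v in pwm.matrix[bi])
                fh.write(f"{b} [ {vals} ]\n")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.int8)  # default: N
    for b, i in _CODE.items():
        code[arr == ord(b)] = i
    return code


def _strand_scores(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Window scores at every start position for one strand; windows
    containing N score -inf."""
    L = log_odds.shape[1]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    lut = np.vstack([log_odds, np.full((1, L), _NEG_INF)])  # row 4 = N
    scores = np.zeros(n)
    for j in range(L):
        scores += lut[code[j : j + n], j]
    return np.maximum(scores, _NEG_INF)


def scan_sequence(seq: str, pwm: PWM) -> tuple[bool, list[tuple[int, str, float]]]:
    """Scan one sequence on both strands.

    Returns (hit, positions): hit iff the best window score on either
    strand reaches ``threshold_fraction * max achievable score``; positions
    lists every (start, strand, score) at or above the threshold.
    """
    L = pwm.length
    if len(seq) < L:
        return False, []
    code = _encode(seq)
    thr = pwm.threshold_fraction * pwm.max_score()
    hits: list[tuple[int, str, float]] = []
    fwd = _strand_scores(code, pwm.log_odds())
    rev = _strand_scores(code, pwm.reverse_complement().log_odds())
    for strand, scores in (("+", fwd), ("-", rev)):
        idx = np.nonzero(scores >= thr)[0]
        hits.extend((int(i), strand, float(scores[i])) for i in idx)
    hits.sort()
    return bool(hits), hits


def scan_sequences(seqs: Sequence[str], pwm: PWM) -> np.ndarray:
    """Boolean hit flag per sequence."""
    return np.asarray([scan_sequence(s, pwm)[0] for s in seqs], dtype=bool)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (Altschul-Erickson: random last-edge spanning tree into the final
    vertex, then random ordering of the remaining edges)."""
    s = seq.upper()
    if len(s) < 3:
        return s
    verts = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    # choose, for every vertex with out-edges except `last`, a final edge such
    # that following final edges always reaches `last`
    for _attempt in range(200):
        final: dict[str, str] = {}
        ok = True
        for v in verts:
            if v == last or not edges[v]:
                continue
            final[v] = edges[v][rng.integers(len(edges[v]))]
        for v in final:
            seen = {v}
            cur = v
            while cur != last:
                if cur not in final:  # dead end without out-edge
                    ok = False
                    break
                cur = final[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:
        return s  # degenerate composition; give up gracefully
    remaining: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v in final:
            pool.remove(final[v])
        rng.shuffle(pool)
        if v in final:
            pool.append(final[v])
        remaining[v] = pool
    out = [s[0]]
    ptr = {v: 0 for v in verts}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = remaining[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(
    fg_seqs: Sequence[str], rng: np.random.Generator, times: int = 2
) -> list[str]:
    """Dinucleotide-shuffled copies of the foreground, ``times`` x count."""
    return [dinucleotide_shuffle(s, rng) for _ in range(times) for s in fg_seqs]


def enrichment_test(fg_seqs: Sequence[str], bg_seqs: Sequence[str], pwm: PWM) -> dict:
    """One-sided hypergeometric enrichment of PWM hits, fg vs fg+bg urn.

    p = P(X >= observed fg hits) for X hypergeometric with population
    fg+bg sequences, of which (fg hits + bg hits) are 'successes', drawing
    |fg| sequences.
    """
    if not fg_seqs:
        raise ValueError("empty foreground")
    fg_hits = int(scan_sequences(fg_seqs, pwm).sum())
    bg_hits = int(scan_sequences(bg_seqs, pwm).sum()) if bg_seqs else 0
    n_fg, n_bg = len(fg_seqs), len(bg_seqs)
    p = float(stats.hypergeom.sf(fg_hits - 1, n_fg + n_bg, fg_hits + bg_hits, n_fg))
    return {
        "fg_hits": fg_hits,
        "n_fg": n_fg,
        "bg_hits": bg_hits,
        "n_bg": n_bg,
        "pvalue": min(1.0, max(p, np.nextafter(0, 1))),
    }


@dataclass
class MotifEnrichmentTable:
    """Long-form per-(motif, cell type, condition) enrichment results."""

    table: pd.DataFrame  # columns: motif_id, cell_type, condition, fg_hits, n_fg, bg_hits, n_bg, pvalue, qvalue

    @classmethod
    def build(
        cls,
        pwms: Sequence[PWM],
        fg_by_group: Mapping[tuple[str, str], Sequence[str]],
        rng: np.random.Generator,
        bg_times: int = 2,
    ) -> "MotifEnrichmentTable":
        rows = []
        for (cell_type, condition), fg in sorted(fg_by_group.items()):
            bg = make_background(fg, rng, times=bg_times)
            for pwm in pwms:
                r = enrichment_test(fg, bg, pwm)
                rows.append(
                    {"motif_id": pwm.motif_id, "cell_type": cell_type,
                     "condition": condition, **r}
                )
        df = pd.DataFrame(rows)
        df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
        return cls(table=df)

    def p(self, motif_id: str, cell_type: str, condition: str) -> float:
        t = self.table
        row = t[
            (t.motif_id == motif_id)
            & (t.cell_type == cell_type)
            & (t.condition == condition)
        ]
        if row.empty:
            raise KeyError((motif_id, cell_type, condition))
        return float(row.iloc[0]["pvalue"])

    def pivot_p(self, condition: str) -> pd.DataFrame:
        """Motifs x cell types p-value matrix for one condition."""
        t = self.table[self.table.condition == condition]
        return t.pivot(index="motif_id", columns="cell_type", values="pvalue")

    def motifs(self) -> list[str]:
        return sorted(self.table.motif_id.unique())


def condition_differential_motifs(
    table: MotifEnrichmentTable, cell_type: str, alpha: float = 1e-4
) -> dict[str, set[str]]:
    """NC-only / shared / MUT-only enriched motifs for one cell type."""
    nc_only, shared, mut_only = set(), set(), set()
    for m in table.motifs():
        p_nc = table.p(m, cell_type, "NC")
        p_mut = table.p(m, cell_type, "MUT")
        if p_nc < alpha and p_mut < alpha:
            shared.add(m)
        elif p_nc < alpha:
            nc_only.add(m)
        elif p_mut < alpha:
            mut_only.add(m)
    return {"NC_only": nc_only, "shared": shared, "MUT_only": mut_only}


def celltype_specific_tfs(
    table: MotifEnrichmentTable,
    cell_types: Sequence[str] = ("BC", "LP", "ML"),
    condition: str = "NC",
    alpha: float = 1e-4,
) -> dict[str, set[str]]:
    """Motifs significantly enriched (p < alpha) in exactly one of the
    given cell types under ``condition``; pairwise disjoint by
    construction."""
    out: dict[str, set[str]] = {ct: set() for ct in cell_types}
    for m in table.motifs():
        sig = [ct for ct in cell_types if table.p(m, ct, condition) < alpha]
        if len(sig) == 1:
            out[sig[0]].add(m)
    return out


def mut_preservation(
    specific_sets: Mapping[str, set[str]],
    table: MotifEnrichmentTable,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """How the NC cell-type-specific TF sets fare in MUT.

    Returns a matrix with rows = MUT cell type X, columns = origin cell
    type Y; entry = number of Y-specific motifs enriched (p < alpha) in
    MUT X.  The diagonal is the preserved count; off-diagonal entries are
    cross-gained counts.
    """
    cts = list(specific_sets)
    mat = pd.DataFrame(0, index=cts, columns=cts, dtype=int)
    for x in cts:
        for y in cts:
            mat.loc[x, y] = sum(
                1 for m in specific_sets[y] if table.p(m, x, "MUT") < alpha
            )
    return mat
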