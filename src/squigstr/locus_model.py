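"""Repeat-expression grammar and k-mer automata for STR loci.

A short tandem repeat (STR) locus is described by a small regular-expression
dialect over IUPAC nucleotide codes:

* plain letters form literal sequence blocks,
* ``{...}`` encloses a block that may be skipped entirely,
* ``(...)`` encloses a block repeated one or more times.

For example the myotonic-dystrophy-type-2 repeat, a CAGG run with occasional
CAGA/CAGC interruptions, is written ``(CAGG{CAGM})`` where ``M`` = A or C.

The expression, together with flanking reference sequence, is compiled into a
base-level finite-state automaton (one nucleotide per state) and then expanded
into k-mer space: each length-k path of the base automaton becomes a state
carrying the expected nanopore current level for its k-mer, looked up in a
pore model table.  The k-mer automaton is what the raw signal is aligned to.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "ExpressionError",
    "PoreModelError",
    "Literal",
    "OptionalBlock",
    "RepeatBlock",
    "RepeatExpression",
    "parse_repeat_expression",
    "reverse_expression",
    "autogenerate_expression",
    "instantiate_expression",
    "reverse_complement",
    "BaseAutomaton",
    "build_base_automaton",
    "KmerAutomaton",
    "expand_to_kmer_automaton",
    "build_locus_automata",
    "PoreModel",
    "load_pore_model",
    "write_pore_model",
]

# IUPAC nucleotide codes -> the concrete nucleotides they stand for.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

ROLE_LEFT = "left_flank"
ROLE_REPEAT = "repeat"
ROLE_RIGHT = "right_flank"


class ExpressionError(ValueError):
    """Malformed repeat expression (position-annotated where possible)."""


class PoreModelError(ValueError):
    """Malformed or incomplete pore-model table."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ExpressionError(f"non-IUPAC symbol {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Expression grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Literal:
    seq: str


@dataclass(frozen=True)
class OptionalBlock:
    blocks: tuple
    opt_id: int


@dataclass(frozen=True)
class RepeatBlock:
    blocks: tuple
    group_id: int


@dataclass(frozen=True)
class RepeatExpression:
    """Parsed repeat expression: an ordered tree of blocks.

    Repeat groups and optional blocks are numbered left to right (by opening
    bracket), densely from 0.
    """

    blocks: tuple
    n_groups: int
    n_optionals: int

    def to_string(self) -> str:
        return _serialize(self.blocks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _serialize(blocks: Sequence) -> str:
    parts = []
    for b in blocks:
        if isinstance(b, Literal):
            parts.append(b.seq)
        elif isinstance(b, OptionalBlock):
            parts.append("{" + _serialize(b.blocks) + "}")
        elif isinstance(b, RepeatBlock):
            parts.append("(" + _serialize(b.blocks) + ")")
        else:  # pragma: no cover
            raise TypeError(type(b))
    return "".join(parts)


def _fully_skippable(blocks: Sequence) -> bool:
    return all(isinstance(b, OptionalBlock) for b in blocks)


def parse_repeat_expression(expr: str) -> RepeatExpression:
    """Parse a repeat expression string.

    Raises :class:`ExpressionError` naming the offending position for
    unbalanced brackets, empty groups or non-IUPAC characters.
    """
    expr = "".join(expr.split())
    if not expr:
        raise ExpressionError("empty expression")
    counters = {"group": 0, "opt": 0}
    pos = 0

    def parse_seq(closing: str | None) -> tuple:
        nonlocal pos
        blocks: list = []
        lit: list[str] = []

        def flush() -> None:
            if lit:
                blocks.append(Literal("".join(lit)))
                lit.clear()

        while pos < len(expr):
            ch = expr[pos]
            if ch == closing:
                flush()
                return tuple(blocks)
            if ch in ")}":
                raise ExpressionError(f"unbalanced {ch!r} at position {pos}")
            if ch == "(":
                flush()
                gid = counters["group"]
                counters["group"] += 1
                open_pos = pos
                pos += 1
                body = parse_seq(")")
                if pos >= len(expr):
                    raise ExpressionError(f"unclosed '(' at position {open_pos}")
                pos += 1
                if not body:
                    raise ExpressionError(f"empty repeat group at position {open_pos}")
                if _fully_skippable(body):
                    raise ExpressionError(
                        f"repeat group at position {open_pos} is entirely optional"
                    )
                blocks.append(RepeatBlock(body, gid))
            elif ch == "{":
                flush()
                oid = counters["opt"]
                counters["opt"] += 1
                open_pos = pos
                pos += 1
                body = parse_seq("}")
                if pos >= len(expr):
                    raise ExpressionError(f"unclosed '{{' at position {open_pos}")
                pos += 1
                if not body:
                    raise ExpressionError(f"empty optional block at position {open_pos}")
                blocks.append(OptionalBlock(body, oid))
            elif ch in IUPAC_CODES:
                lit.append(ch)
                pos += 1
            else:
                raise ExpressionError(f"non-IUPAC character {ch!r} at position {pos}")
        flush()
        if closing is not None:
            raise ExpressionError("unbalanced bracket: input ended inside a group")
        return tuple(blocks)

    blocks = parse_seq(None)
    return RepeatExpression(blocks, counters["group"], counters["opt"])


def _reverse_blocks(blocks: Sequence) -> tuple:
    out = []
    for b in reversed(blocks):
        if isinstance(b, Literal):
            out.append(Literal(reverse_complement(b.seq)))
        elif isinstance(b, OptionalBlock):
            out.append(OptionalBlock(_reverse_blocks(b.blocks), b.opt_id))
        else:
            out.append(RepeatBlock(_reverse_blocks(b.blocks), b.group_id))
    return tuple(out)


def reverse_expression(expr: RepeatExpression) -> RepeatExpression:
    """Reverse-complement an expression, preserving group/optional ids.

    The reverse-strand model of a locus is the forward construction applied to
    the reverse-complemented, order-reversed expression.
    """
    return RepeatExpression(_reverse_blocks(expr.blocks), expr.n_groups, expr.n_optionals)


def autogenerate_expression(region: str, motif: str, min_copies: int = 1) -> str:
    """Derive a repeat expression from a reference STR region and its motif.

    Scans left to right; each maximal run of at least ``min_copies`` exact
    motif copies becomes a ``(motif)`` group, everything between runs stays a
    literal block.  Instantiating the result with the observed copy numbers
    reproduces ``region`` exactly.  If the motif never occurs, the region is
    returned verbatim (with a warning) as one literal block.
    """
    if not motif:
        raise ExpressionError("empty motif")
    if not region:
        raise ExpressionError("empty region")
    if motif not in region:
        warnings.warn(
            f"motif {motif!r} not found in region; using the region as a literal block",
            stacklevel=2,
        )
        return region
    parts: list[str] = []
    lit: list[str] = []
    i = 0
    w = len(motif)
    while i < len(region):
        copies = 0
        while region.startswith(motif, i + copies * w):
            copies += 1
        if copies >= max(min_copies, 1):
            if lit:
                parts.append("".join(lit))
                lit.clear()
            parts.append(f"({motif})")
            i += copies * w
        else:
            lit.append(region[i])
            i += 1
    if lit:
        parts.append("".join(lit))
    return "".join(parts)


def instantiate_expression(
    expr: RepeatExpression | str,
    repeat_counts: Mapping[int, int] | int,
    include_optionals: bool = False,
) -> str:
    """Spell out one concrete word of an expression.

    Each repeat group ``g`` is traversed ``repeat_counts[g]`` times (or a
    single integer for all groups); optional blocks are included in every
    traversal iff ``include_optionals``.  IUPAC ambiguity codes resolve to
    their first concrete nucleotide (deterministic).
    """
    if isinstance(expr, str):
        expr = parse_repeat_expression(expr)
    if isinstance(repeat_counts, int):
        counts = {g: repeat_counts for g in range(expr.n_groups)}
    else:
        counts = dict(repeat_counts)

    def spell(blocks: Sequence) -> str:
        out = []
        for b in blocks:
            if isinstance(b, Literal):
                out.append("".join(IUPAC_CODES[c][0] for c in b.seq))
            elif isinstance(b, OptionalBlock):
                if include_optionals:
                    out.append(spell(b.blocks))
            else:
                c = counts.get(b.group_id, 1)
                if c < 1:
                    raise ValueError(f"repeat group {b.group_id} needs >=1 traversal")
                out.append(spell(b.blocks) * c)
        return "".join(out)

    return spell(expr.blocks)


# ---------------------------------------------------------------------------
# Base automaton (one nucleotide per state)
# ---------------------------------------------------------------------------

@dataclass
class BaseState:
    idx: int
    symbol: str           # IUPAC symbol
    role: str             # left_flank | repeat | right_flank
    group_id: int | None  # innermost owning repeat group


class BaseAutomaton:
    """Nucleotide-level finite-state automaton for a flanked STR locus.

    The accepted language is ``left_flank . w . right_flank`` for every word
    ``w`` matching the repeat expression.  Repeat groups carry a back
    transition realizing "at least once, arbitrarily many"; optional blocks
    are bypassed by direct edges.
    """

    def __init__(self) -> None:
        self.states: list[BaseState] = []
        self.succ: list[list[int]] = []
        self.starts: set[int] = set()
        self.accepts: set[int] = set()
        self.group_states: dict[int, set[int]] = {}
        self.group_entries: dict[int, set[int]] = {}
        self.group_backedges: dict[int, set[tuple[int, int]]] = {}
        self.opt_states: dict[int, set[int]] = {}
        self.opt_entries: dict[int, set[int]] = {}
        # edge -> list of ("group"|"optional", id) counters it increments
        self.unit_increments: dict[tuple[int, int], list[tuple[str, int]]] = {}

    # -- construction helpers -------------------------------------------------
    def _new_state(self, symbol: str, role: str, groups: Sequence[int], opts: Sequence[int]) -> int:
        idx = len(self.states)
        gid = groups[-1] if groups else None
        self.states.append(BaseState(idx, symbol, role, gid))
        self.succ.append([])
        for g in groups:
            self.group_states.setdefault(g, set()).add(idx)
        for o in opts:
            self.opt_states.setdefault(o, set()).add(idx)
        return idx

    def _add_edge(self, u: int, v: int) -> None:
        if v not in self.succ[u]:
            self.succ[u].append(v)

    def _finalize(self) -> None:
        for u in range(len(self.states)):
            self.succ[u].sort()
        # unit-count increments: crossing a repeat group's entry boundary, or
        # entering an optional block from outside it
        for g, entries in self.group_entries.items():
            members = self.group_states[g]
            back = self.group_backedges[g]
            for u in range(len(self.states)):
                for v in self.succ[u]:
                    if v in entries and (u not in members or (u, v) in back):
                        self.unit_increments.setdefault((u, v), []).append(("group", g))
        for o, entries in self.opt_entries.items():
            members = self.opt_states[o]
            for u in range(len(self.states)):
                for v in self.succ[u]:
                    if v in entries and u not in members:
                        self.unit_increments.setdefault((u, v), []).append(("optional", o))

    # -- queries --------------------------------------------------------------
    def n_states(self) -> int:
        return len(self.states)

    def accepts_word(self, word: str) -> bool:
        active = {s for s in self.starts if word and word[0] in IUPAC_CODES[self.states[s].symbol]}
        for ch in word[1:]:
            active = {
                v for u in active for v in self.succ[u]
                if ch in IUPAC_CODES[self.states[v].symbol]
            }
            if not active:
                return False
        return bool(active & self.accepts)

    def shortest_accepted_word(self) -> str:
        """Shortest accepted word (BFS; IUPAC resolved to first nucleotide)."""
        prev: dict[int, tuple[int | None, str]] = {}
        q: deque[int] = deque()
        for s in sorted(self.starts):
            prev[s] = (None, IUPAC_CODES[self.states[s].symbol][0])
            q.append(s)
        goal = None
        while q:
            u = q.popleft()
            if u in self.accepts:
                goal = u
                break
            for v in self.succ[u]:
                if v not in prev:
                    prev[v] = (u, IUPAC_CODES[self.states[v].symbol][0])
                    q.append(v)
        if goal is None:
            raise ExpressionError("automaton accepts no word")
        chars = []
        cur: int | None = goal
        while cur is not None:
            p, ch = prev[cur]
            chars.append(ch)
            cur = p
        return "".join(reversed(chars))

    def language_upto(self, max_len: int) -> set[str]:
        """All accepted words of length <= max_len (exhaustive; tests only)."""
        out: set[str] = set()
        stack: list[tuple[int, str]] = []
        for s in sorted(self.starts):
            for c in IUPAC_CODES[self.states[s].symbol]:
                stack.append((s, c))
        while stack:
            u, word = stack.pop()
            if u in self.accepts:
                out.add(word)
            if len(word) >= max_len:
                continue
            for v in self.succ[u]:
                for c in IUPAC_CODES[self.states[v].symbol]:
                    stack.append((v, word + c))
        return out


class _Fragment:
    __slots__ = ("ins", "outs", "skippable")

    def __init__(self, ins: set[int], outs: set[int], skippable: bool):
        self.ins = ins
        self.outs = outs
        self.skippable = skippable


def _compile_blocks(
    auto: BaseAutomaton,
    blocks: Sequence,
    role: str,
    groups: list[int],
    opts: list[int],
) -> _Fragment:
    ins: set[int] = set()
    cur_outs: set[int] = set()
    all_skippable = True
    for b in blocks:
        if isinstance(b, Literal):
            first = prev = auto._new_state(b.seq[0], role, groups, opts)
            for ch in b.seq[1:]:
                nxt = auto._new_state(ch, role, groups, opts)
                auto._add_edge(prev, nxt)
                prev = nxt
            frag = _Fragment({first}, {prev}, False)
        elif isinstance(b, OptionalBlock):
            frag = _compile_blocks(auto, b.blocks, role, groups, opts + [b.opt_id])
            auto.opt_entries.setdefault(b.opt_id, set()).update(frag.ins)
            frag = _Fragment(frag.ins, frag.outs, True)
        elif isinstance(b, RepeatBlock):
            frag = _compile_blocks(auto, b.blocks, role, groups + [b.group_id], opts)
            if frag.skippable:
                raise ExpressionError(
                    f"repeat group {b.group_id} may not be entirely optional"
                )
            auto.group_entries.setdefault(b.group_id, set()).update(frag.ins)
            back = auto.group_backedges.setdefault(b.group_id, set())
            for u in frag.outs:
                for v in frag.ins:
                    auto._add_edge(u, v)
                    back.add((u, v))
        else:  # pragma: no cover
            raise TypeError(type(b))
        for u in cur_outs:
            for v in frag.ins:
                auto._add_edge(u, v)
        if all_skippable:
            ins |= frag.ins
        if frag.skippable:
            cur_outs = cur_outs | frag.outs
        else:
            cur_outs = set(frag.outs)
        all_skippable = all_skippable and frag.skippable
    return _Fragment(ins, cur_outs, all_skippable)


def build_base_automaton(
    expr: RepeatExpression | str,
    left_flank: str,
    right_flank: str,
) -> BaseAutomaton:
    """Compile a repeat expression plus flanks into a base automaton."""
    if isinstance(expr, str):
        expr = parse_repeat_expression(expr)
    for name, flank in (("left", left_flank), ("right", right_flank)):
        if not flank or any(c not in "ACGT" for c in flank):
            raise ExpressionError(f"{name} flank must be non-empty A/C/G/T sequence")
    auto = BaseAutomaton()
    lfrag = _compile_blocks(auto, (Literal(left_flank),), ROLE_LEFT, [], [])
    efrag = _compile_blocks(auto, expr.blocks, ROLE_REPEAT, [], [])
    rfrag = _compile_blocks(auto, (Literal(right_flank),), ROLE_RIGHT, [], [])
    for u in lfrag.outs:
        for v in efrag.ins:
            auto._add_edge(u, v)
        if efrag.skippable:
            for v in rfrag.ins:
                auto._add_edge(u, v)
    for u in efrag.outs:
        for v in rfrag.ins:
            auto._add_edge(u, v)
    auto.starts = set(lfrag.ins)
    auto.accepts = set(rfrag.outs)
    auto._finalize()
    return auto


# ---------------------------------------------------------------------------
# Pore model
# ---------------------------------------------------------------------------

@dataclass
class PoreModel:
    """k-mer -> expected current level lookup (complete over {A,C,G,T}^k)."""

    k: int
    levels: dict[str, float]
    stdvs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        expected = 4 ** self.k
        if len(self.levels) != expected:
            raise PoreModelError(
                f"pore model for k={self.k} needs {expected} k-mers, "
                f"got {len(self.levels)} ({expected - len(self.levels)} missing or extra)"
            )
        for kmer in self.levels:
            if len(kmer) != self.k or any(c not in "ACGT" for c in kmer):
                raise PoreModelError(f"invalid k-mer {kmer!r} for k={self.k}")

    def level(self, kmer: str) -> float:
        return self.levels[kmer]

    def normalized(self) -> "PoreModel":
        """Median-normalized copy, on the same scale as normalized signal.

        Applies the same shift/scale statistics used for raw-signal
        normalization (mid-percentile shift, median absolute deviation scale)
        to the table itself, so expected levels and normalized signal values
        are directly comparable.
        """
        vals = np.array(list(self.levels.values()))
        shift = 0.5 * (np.percentile(vals, 46.5) + np.percentile(vals, 53.5))
        scale = float(np.median(np.abs(vals - shift)))
        if scale == 0:
            raise PoreModelError("degenerate pore model: zero level spread")
        levels = {kmer: (v - shift) / scale for kmer, v in self.levels.items()}
        stdvs = None
        if self.stdvs is not None:
            stdvs = {kmer: v / scale for kmer, v in self.stdvs.items()}
        return PoreModel(self.k, levels, stdvs)


def load_pore_model(path) -> PoreModel:
    """Read an ONT-style tab-separated pore model (``kmer<TAB>level_mean...``)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    kcol = cols.get("kmer", df.columns[0])
    lcol = cols.get("level_mean", df.columns[1] if len(df.columns) > 1 else None)
    if lcol is None:
        raise PoreModelError("pore model needs a level column")
    kmers = df[kcol].astype(str)
    lengths = kmers.str.len().unique()
    if len(lengths) != 1:
        raise PoreModelError(f"inconsistent k-mer lengths in pore model: {sorted(lengths)}")
    k = int(lengths[0])
    levels = dict(zip(kmers, df[lcol].astype(float)))
    if len(levels) != len(df):
        raise PoreModelError("duplicate k-mers in pore model")
    stdvs = None
    if "level_stdv" in cols:
        stdvs = dict(zip(kmers, df[cols["level_stdv"]].astype(float)))
    return PoreModel(k, levels, stdvs)


def write_pore_model(model: PoreModel, path) -> None:
    rows = {"kmer": sorted(model.levels)}
    rows["level_mean"] = [model.levels[k] for k in rows["kmer"]]
    if model.stdvs is not None:
        rows["level_stdv"] = [model.stdvs[k] for k in rows["kmer"]]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# k-mer automaton
# ---------------------------------------------------------------------------

class KmerAutomaton:
    """Expansion of a base automaton into k-mer space.

    Each state is a (concrete k-mer, base end state) pair: a length-k path of
    the base automaton with IUPAC symbols instantiated.  Two states are
    connected when their k-mers overlap by k-1 and the base transition exists.
    States inherit role/group annotations from their most recent base and
    carry the expected current level from the pore model.
    """

    def __init__(self, k: int, base: BaseAutomaton):
        self.k = k
        self.base = base
        self.kmers: list[str] = []
        self.base_state: list[int] = []
        self.succ: list[list[int]] = []
        self.pred: list[list[int]] = []
        self.starts: list[int] = []
        self.accepts: list[int] = []
        self.levels: np.ndarray = np.empty(0)
        self.roles: list[str] = []
        self.group_ids: list[int | None] = []

    def n_states(self) -> int:
        return len(self.kmers)

    def role_codes(self) -> np.ndarray:
        order = {ROLE_LEFT: 0, ROLE_REPEAT: 1, ROLE_RIGHT: 2}
        return np.array([order[r] for r in self.roles], dtype=np.int8)

    def pred_matrix(self) -> np.ndarray:
        """Predecessor sets as a padded (n, P) index matrix.

        Rows are padded with index n (a virtual state of infinite cost);
        predecessors are listed in lexicographic (k-mer, base state) order so
        that "first argmin" tie-breaking is deterministic.
        """
        n = self.n_states()
        width = max((len(p) for p in self.pred), default=1) or 1
        mat = np.full((n, width), n, dtype=np.int64)
        for j, preds in enumerate(self.pred):
            mat[j, : len(preds)] = preds
        return mat

    def transition_units(self, a: int, b: int) -> list[tuple[str, int]]:
        """Repeat-group / optional counters incremented by k-mer edge a->b."""
        return self.base.unit_increments.get((self.base_state[a], self.base_state[b]), [])


def expand_to_kmer_automaton(base: BaseAutomaton, model: PoreModel) -> KmerAutomaton:
    """Expand a base automaton into k-mer space with expected levels.

    ``k`` is taken from the pore model.  IUPAC symbols expand into one state
    per concrete nucleotide choice, so every state has a defined level.
    Requires flanks of length >= k so the start context is well defined.
    """
    k = model.k
    auto = KmerAutomaton(k, base)
    key_to_idx: dict[tuple[str, int], int] = {}

    def get_state(kmer: str, bstate: int) -> int:
        key = (kmer, bstate)
        idx = key_to_idx.get(key)
        if idx is None:
            idx = len(auto.kmers)
            key_to_idx[key] = idx
            auto.kmers.append(kmer)
            auto.base_state.append(bstate)
            auto.succ.append([])
            auto.pred.append([])
            st = base.states[bstate]
            auto.roles.append(st.role)
            auto.group_ids.append(st.group_id)
        return idx

    # enumerate all length-k paths starting at a base start state
    initial: list[tuple[str, int]] = []
    stack: list[tuple[int, str]] = []
    for s in sorted(base.starts):
        for c in IUPAC_CODES[base.states[s].symbol]:
            stack.append((s, c))
    while stack:
        u, prefix = stack.pop()
        if len(prefix) == k:
            initial.append((prefix, u))
            continue
        for v in base.succ[u]:
            for c in IUPAC_CODES[base.states[v].symbol]:
                stack.append((v, prefix + c))
    if not initial:
        raise ExpressionError(
            f"flank shorter than k={k}: start context undefined"
        )
    queue: deque[int] = deque()
    for kmer, bstate in sorted(initial):
        idx = get_state(kmer, bstate)
        if idx not in auto.starts:
            auto.starts.append(idx)
            queue.append(idx)
    seen = set(auto.starts)
    while queue:
        cur = queue.popleft()
        kmer = auto.kmers[cur]
        u = auto.base_state[cur]
        for v in base.succ[u]:
            for c in IUPAC_CODES[base.states[v].symbol]:
                child = get_state(kmer[1:] + c, v)
                if child not in auto.succ[cur]:
                    auto.succ[cur].append(child)
                    auto.pred[child].append(cur)
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
    auto.levels = np.array([model.level(km) for km in auto.kmers])
    auto.accepts = sorted(
        (j for j in range(auto.n_states()) if auto.base_state[j] in base.accepts),
        key=lambda j: (auto.kmers[j], auto.base_state[j]),
    )
    for j in range(auto.n_states()):
        auto.pred[j].sort(key=lambda p: (auto.kmers[p], auto.base_state[p]))
        auto.succ[j].sort(key=lambda s: (auto.kmers[s], auto.base_state[s]))
    auto.starts.sort(key=lambda j: (auto.kmers[j], auto.base_state[j]))
    return auto


def build_locus_automata(
    expr: RepeatExpression | str,
    left_flank: str,
    right_flank: str,
    model: PoreModel,
) -> dict[str, KmerAutomaton]:
    """Forward ('+') and reverse ('-') strand k-mer automata for a locus.

    The reverse automaton is the forward construction applied to the
    reverse-complemented expression with swapped, reverse-complemented flanks;
    a read's mapped strand selects which automaton its signal is aligned to.
    """
    if isinstance(expr, str):
        expr = parse_repeat_expression(expr)
    fwd = expand_to_kmer_automaton(build_base_automaton(expr, left_flank, right_flank), model)
    rev = expand_to_kmer_automaton(
        build_base_automaton(
            reverse_expression(expr),
            reverse_complement(right_flank),
            reverse_complement(left_flank),
        ),
        model,
    )
    return {"+": fwd, "-": rev}
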