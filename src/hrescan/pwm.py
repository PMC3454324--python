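"""Position weight matrices and information-content-weighted scoring.

A PWM is built from raw base counts ``f(b, i)`` (bases A/C/G/T down the
rows, motif positions along the columns).  Counts are converted to
pseudocount-corrected probabilities

    p(b, i) = (f(b, i) + c * p(b)) / (N_i + c)

where ``p(b)`` is the background base distribution, ``N_i`` the number of
aligned sites in column ``i`` and ``c`` a pseudocount weight (default
``sqrt(N_i)``, distributed according to the background).  Log-odds weights
are ``W(b, i) = log2(p(b, i) / p(b))`` and the per-position information
content is the relative entropy versus background,

    D_i = sum_b p(b, i) * log2(p(b, i) / p(b))   [bits],

after Stormo.  A window of length L scores

    S = sum_i D_i * W(b_i, i)

i.e. each position's log-odds contribution is weighted by how informative
that position is.  Scores are min-max normalized to [0, 1] using the best
and worst attainable window scores.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

# byte -> base code lookup; anything unrecognized (incl. N) maps to 4
_CODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return "".join(_RC.get(c.upper(), "N") for c in reversed(seq))


class PWMParseError(ValueError):
    """Raised when a motif document cannot be parsed."""


class PWMValidationError(ValueError):
    """Raised when parsed matrix content is invalid (e.g. negative counts)."""


def corrected_probability(counts_column, N=None, background=None, pseudocount_weight=None):
    """Pseudocount-corrected base probabilities for one matrix column.

    p(b) = (f(b) + c*bg(b)) / (N + c).  ``pseudocount_weight`` defaults to
    sqrt(N); ``N`` defaults to the column sum.
    """
    counts = np.asarray(counts_column, dtype=float)
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-6:
        raise PWMValidationError("background probabilities must sum to 1")
    if N is None:
        N = counts.sum()
    if N <= 0:
        raise PWMValidationError("column total N must be positive")
    c = math.sqrt(N) if pseudocount_weight is None else float(pseudocount_weight)
    if c < 0:
        raise PWMValidationError("pseudocount weight must be non-negative")
    return (counts + c * background) / (N + c)


def _relative_entropy(p: np.ndarray, background: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / background[nz])))


@dataclass
class ScoredWindow:
    sequence: str
    raw_score: float
    normalized_score: float
    unscannable: bool = False  # window contained N / unknown base


@dataclass
class PWM:
    """A position weight matrix with derived scoring machinery.

    Parameters
    ----------
    id, name : identifiers from the source database record.
    counts : (4, L) array of raw base counts, rows in A, C, G, T order.
    background : base probabilities (default uniform).
    pseudocount : pseudocount weight c; ``None`` means sqrt(N_i) per column.
    ic_fraction : fraction of the maximal attainable information content a
        position must reach for its ``ic_mask`` entry to be set (the mask
        drives the conservation filter downstream).
    """

    id: str
    name: str = ""
    counts: np.ndarray = None
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float | None = None
    ic_fraction: float = 0.60

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise PWMValidationError(f"{self.id}: counts must be a 4 x L matrix")
        if np.any(self.counts < 0):
            raise PWMValidationError(f"{self.id}: negative counts")
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise PWMValidationError(f"{self.id}: background must sum to 1")
        self.column_totals = self.counts.sum(axis=0)
        if np.any(self.column_totals <= 0):
            raise PWMValidationError(f"{self.id}: empty matrix column")
        probs = np.empty_like(self.counts)
        for i in range(self.length):
            probs[:, i] = corrected_probability(
                self.counts[:, i],
                N=self.column_totals[i],
                background=self.background,
                pseudocount_weight=self.pseudocount,
            )
        self.probs = probs
        with np.errstate(divide="ignore"):
            self.weights = np.log2(probs / self.background[:, None])
        self.ic = np.array(
            [_relative_entropy(probs[:, i], self.background) for i in range(self.length)]
        )
        # maximal attainable relative entropy given this background
        self.ic_max = -math.log2(float(self.background.min()))
        self.ic_mask = self.ic / self.ic_max >= self.ic_fraction
        # scoring matrix: IC-weighted log-odds.  Columns with zero IC
        # contribute nothing (guards 0 * -inf).
        sm = self.weights * self.ic[None, :]
        sm[:, self.ic == 0] = 0.0
        self.score_matrix = sm
        finite = np.where(np.isfinite(sm), sm, np.inf)
        self.score_min = float(np.min(finite, axis=0).sum())
        self.score_max = float(np.max(np.where(np.isfinite(sm), sm, -np.inf), axis=0).sum())

    # -- basic geometry ------------------------------------------------
    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.probs, axis=0))

    # -- scoring -------------------------------------------------------
    def _normalize(self, raw: np.ndarray) -> np.ndarray:
        rng = self.score_max - self.score_min
        if rng == 0:
            # degenerate matrix: every window is equally good
            return np.ones_like(raw, dtype=float)
        norm = (raw - self.score_min) / rng
        norm = np.where(np.isfinite(raw), norm, 0.0)
        return np.clip(norm, 0.0, 1.0)

    def score(self, window: str) -> ScoredWindow:
        """Score one window of length L (the IC-weighted log-odds sum)."""
        if len(window) != self.length:
            raise ValueError(
                f"window length {len(window)} != matrix length {self.length}"
            )
        codes = encode(window)
        if np.any(codes == 4):
            return ScoredWindow(window, float("nan"), 0.0, unscannable=True)
        raw = float(self.score_matrix[codes, np.arange(self.length)].sum())
        return ScoredWindow(window, raw, float(self._normalize(np.array([raw]))[0]))

    def scan_codes(self, codes: np.ndarray, reverse: bool = False) -> np.ndarray:
        """Normalized scores for every window of an encoded sequence.

        With ``reverse=True`` each window is scored as its reverse
        complement (minus-strand scan reported at plus-strand offsets).
        Windows containing unknown bases score 0.
        """
        L = self.length
        if codes.size < L:
            return np.zeros(0)
        sm = self.score_matrix
        if reverse:
            sm = sm[::-1, ::-1]
        sm_pad = np.vstack([np.nan_to_num(sm, neginf=-1e12), np.zeros(sm.shape[1])])
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        raw = sm_pad[win, np.arange(L)].sum(axis=1)
        norm = self._normalize(raw)
        norm[(win == 4).any(axis=1)] = 0.0
        return norm

    def scan(self, seq: str, reverse: bool = False) -> np.ndarray:
        return self.scan_codes(encode(seq), reverse=reverse)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n sequences (as a (n, L) code array) position-wise from
        the corrected probabilities p(., i)."""
        out = np.empty((n, self.length), dtype=np.int8)
        for i in range(self.length):
            out[:, i] = rng.choice(4, size=n, p=self.probs[:, i])
        return out


def log_odds(pwm: PWM) -> np.ndarray:
    """The matrix of log2 odds weights W(b, i) stored on the PWM."""
    return pwm.weights


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position relative entropy versus background, in bits."""
    return pwm.ic


# -- parsers -----------------------------------------------------------


def parse_jaspar(text: str, **pwm_kwargs) -> list[PWM]:
    """Parse JASPAR PFM records (">ID name" header, four base rows).

    Rows may be labeled ("A [ 4 0 ]", "A 4 0") or bare; brackets are
    optional.  Bare rows are taken in A, C, G, T order.
    """
    records: list[PWM] = []
    header = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        rec_id, _, name = header.partition(" ")
        if len(rows) != 4:
            raise PWMParseError(f"record {rec_id!r}: expected 4 base rows, got {len(rows)}")
        counts = np.zeros((4, len(rows[0][1])))
        for k, (label, values) in enumerate(rows):
            base = label if label is not None else BASES[k]
            if base not in _BASE_INDEX:
                raise PWMParseError(f"record {rec_id!r}: unknown base row {base!r}")
            if len(values) != counts.shape[1]:
                raise PWMParseError(
                    f"record {rec_id!r}: row {base} has {len(values)} columns, "
                    f"expected {counts.shape[1]}"
                )
            counts[_BASE_INDEX[base]] = values
        if np.any(counts < 0):
            raise PWMValidationError(f"record {rec_id!r}: negative counts")
        records.append(PWM(id=rec_id, name=name.strip(), counts=counts, **pwm_kwargs))
        header, rows = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            rows = []
            continue
        if header is None:
            raise PWMParseError(f"matrix row before any '>' header: {line!r}")
        tokens = line.replace("[", " ").replace("]", " ").split()
        label = None
        if tokens and tokens[0].upper() in _BASE_INDEX and not tokens[0].isdigit():
            label = tokens[0].upper()
            tokens = tokens[1:]
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise PWMParseError(f"record {header.split()[0]!r}: bad count in {line!r}") from exc
        rows.append((label, values))
    flush()
    return records


def parse_transfac(text: str, **pwm_kwargs) -> list[PWM]:
    """Parse TRANSFAC flat-file matrix records (AC/ID/P0 rows, '//' ends).

    The per-row consensus column is ignored; the record id is taken from
    the AC line.
    """
    if not text.strip():
        return []
    # Bio.motifs silently drops a trailing record with no '//' terminator;
    # treat that as a parse error instead.
    tail = text.rsplit("//", 1)[-1] if "//" in text else text
    if any(ln.strip().startswith("AC") for ln in tail.splitlines()):
        raise PWMParseError("TRANSFAC record missing '//' terminator")
    try:
        bio = list(_bio_motifs.parse(io.StringIO(text), "transfac"))
    except ValueError as exc:
        raise PWMValidationError(f"invalid TRANSFAC matrix content: {exc}") from exc
    out = []
    for m in bio:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        if np.any(counts < 0):
            raise PWMValidationError(f"record {m.get('AC')!r}: negative counts")
        out.append(
            PWM(id=m.get("AC", ""), name=m.get("ID", "") or "", counts=counts, **pwm_kwargs)
        )
    return out


def weights_table(pwms: list[PWM]) -> str:
    """TSV dump of log-odds weights and IC per PWM (one row per position)."""
    lines = ["pwm_id\tposition\tic_bits\tic_masked\tW_A\tW_C\tW_G\tW_T"]
    for p in pwms:
        for i in range(p.length):
            w = "\t".join(f"{p.weights[b, i]:.6g}" for b in range(4))
            lines.append(f"{p.id}\t{i}\t{p.ic[i]:.6g}\t{int(p.ic_mask[i])}\t{w}")
    return "\n".join(lines) + "\n"
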