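"""Position weight matrices: parsing, log-odds transforms and window scoring.

A PWM models a transcription-factor binding motif as independent per-position
nucleotide probabilities.  Scoring a window of sequence against the motif sums
per-position log2 odds against a background nucleotide model, yielding a score
in bits; this is the quantity whose null distribution is calibrated in
:mod:`phylofoot.calibration`.

Supported collection dialects: TRANSFAC flat matrix files (ID/P0 count rows),
JASPAR (">id name" plus four letter rows), UNIPROBE (letter-prefixed
probability rows), and a generic ">id" + four-column dialect for user
matrices.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
#: Complement permutation over the fixed A,C,G,T axis.
_COMPLEMENT = np.array([3, 2, 1, 0])

DEFAULT_PSEUDOCOUNT = 1.0
#: Scale applied when regularizing matrices supplied as probabilities
#: (UNIPROBE): a unit-sum column is treated as this many observations.
PROBABILITY_SCALE = 100.0


class PwmError(ValueError):
    """Raised for malformed matrices or collection records."""


class UnscoreableWindow(Exception):
    """Signal that a window contains characters (N, gaps, ambiguity codes)
    for which a log-odds score is undefined."""


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order background nucleotide distribution (A, C, G, T)."""

    probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise PwmError("background must have 4 nucleotide probabilities")
        if abs(p.sum() - 1.0) > 1e-12:
            raise PwmError("background probabilities must sum to 1")
        if (p <= 0).any():
            raise PwmError("background probabilities must be positive")
        object.__setattr__(self, "probs", p)


UNIFORM_BG = BackgroundModel()


@dataclass
class PositionWeightMatrix:
    """Per-position nucleotide probabilities of a binding motif.

    ``probs`` has shape (W, 4) in fixed A,C,G,T order; every column (motif
    position) sums to 1 and is strictly positive after pseudocount
    regularization.
    """

    id: str
    probs: np.ndarray
    names: list[str] = field(default_factory=list)
    source_dialect: str = "generic"

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise PwmError(f"{self.id}: probs must be W x 4 with W >= 1")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise PwmError(f"{self.id}: matrix columns must sum to 1")
        self.probs = p

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(NUCLEOTIDES[i] for i in self.probs.argmax(axis=1))


@dataclass
class LogOddsMatrix:
    """log2(P(base|PWM) / P(base|background)) per position, in bits."""

    pwm_id: str
    weights: np.ndarray  # (W, 4)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(self.pwm_id, self.weights[::-1, _COMPLEMENT].copy())

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


def counts_to_probabilities(
    counts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: BackgroundModel = UNIFORM_BG,
) -> np.ndarray:
    """Convert a (W, 4) count matrix to probabilities.

    The pseudocount is distributed proportionally to the background:
    ``p = (c + pseudocount * bg) / (colsum + pseudocount)``, guaranteeing
    strictly positive probabilities (hence finite log-odds) whenever the
    pseudocount is positive.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise PwmError("counts must be W x 4")
    if (c < 0).any():
        raise PwmError("counts must be non-negative")
    if pseudocount < 0:
        raise PwmError("pseudocount must be non-negative")
    colsum = c.sum(axis=1)
    if ((colsum + pseudocount) <= 0).any():
        raise PwmError(
            "all-zero count column with zero pseudocount: log-odds undefined; "
            "use a positive pseudocount"
        )
    return (c + pseudocount * background.probs) / (colsum + pseudocount)[:, None]


def log_odds_transform(
    pwm: PositionWeightMatrix, bg: BackgroundModel = UNIFORM_BG
) -> LogOddsMatrix:
    """Build the bits-scaled log-odds scoring matrix of ``pwm`` against ``bg``."""
    if (pwm.probs <= 0).any():
        raise PwmError(
            f"{pwm.id}: zero probability encountered; apply a pseudocount "
            "before the log-odds transform"
        )
    return LogOddsMatrix(pwm.id, np.log2(pwm.probs / bg.probs))


def score_window(lom: LogOddsMatrix, window: str) -> float:
    """Score one sequence window of length W, in bits.

    Raises :class:`UnscoreableWindow` for windows containing gaps, N or any
    other IUPAC ambiguity character: no numeric score is defined there.
    """
    if len(window) != lom.width:
        raise PwmError(
            f"window length {len(window)} != matrix width {lom.width}"
        )
    total = 0.0
    for w, ch in enumerate(window.upper()):
        idx = _NUC_INDEX.get(ch)
        if idx is None:
            raise UnscoreableWindow(f"unscoreable character {ch!r} at offset {w}")
        total += lom.weights[w, idx]
    return float(total)


def reverse_complement_pwm(pwm: PositionWeightMatrix) -> PositionWeightMatrix:
    """Motif on the opposite strand: columns reversed, A<->T and C<->G swapped."""
    return PositionWeightMatrix(
        id=pwm.id,
        probs=pwm.probs[::-1, _COMPLEMENT].copy(),
        names=list(pwm.names),
        source_dialect=pwm.source_dialect,
    )


def matrix_stats(
    pwm: PositionWeightMatrix, bg: BackgroundModel = UNIFORM_BG
) -> dict:
    """Information content (bits, relative to ``bg``) and mean G+C fraction."""
    ic = float(np.sum(pwm.probs * np.log2(pwm.probs / bg.probs)))
    gc = float(np.mean(pwm.probs[:, 1] + pwm.probs[:, 2]))
    return {"information_content": ic, "gc_content": gc}


# ---------------------------------------------------------------------------
# Collection parsing / writing


def _as_stream(source) -> io.TextIOBase:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _finish_matrix(record_id, names, rows, pseudocount, background, dialect,
                   record_index, as_probabilities=False):
    if len(rows) == 0:
        raise PwmError(f"record {record_index} ({record_id}): no matrix rows")
    counts = np.asarray(rows, dtype=float)
    if as_probabilities:
        colsum = counts.sum(axis=1)
        if (colsum <= 0).any():
            raise PwmError(f"record {record_index} ({record_id}): zero column")
        counts = counts / colsum[:, None] * PROBABILITY_SCALE
    probs = counts_to_probabilities(counts, pseudocount, background)
    return PositionWeightMatrix(
        id=record_id, probs=probs, names=names, source_dialect=dialect
    )


def _parse_transfac(stream, pseudocount, background):
    pwms = []
    record_id = None
    names: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    seen_record = False
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tag = line[:2]
        if tag == "//":
            if seen_record:
                pwms.append(_finish_matrix(
                    record_id or f"record{len(pwms) + 1}", names, rows,
                    pseudocount, background, "transfac", len(pwms) + 1))
            record_id, names, rows, in_matrix, seen_record = None, [], [], False, False
        elif tag in ("ID", "AC"):
            if record_id is None:
                record_id = line[2:].strip().split()[0]
            seen_record = True
        elif tag == "NA":
            names.extend(n for n in re.split(r"[;,]\s*", line[2:].strip()) if n)
            seen_record = True
        elif tag in ("P0", "PO"):
            in_matrix = True
            seen_record = True
        elif in_matrix and re.match(r"^\d+\s", line):
            fields = line.split()
            try:
                rows.append([float(x) for x in fields[1:5]])
            except (ValueError, IndexError):
                raise PwmError(
                    f"record {len(pwms) + 1}: malformed TRANSFAC matrix row "
                    f"at line {lineno}: {line!r}") from None
            seen_record = True
    if seen_record:
        pwms.append(_finish_matrix(
            record_id or f"record{len(pwms) + 1}", names, rows,
            pseudocount, background, "transfac", len(pwms) + 1))
    return pwms


def _parse_letter_rows(stream, dialect, pseudocount, background):
    """JASPAR-style (and UNIPROBE-style) letter-prefixed matrices."""
    pwms = []
    record_id = None
    names: list[str] = []
    letter_rows: dict[str, list[float]] = {}

    def flush(lineno):
        nonlocal record_id, names, letter_rows
        if record_id is None and not letter_rows:
            return
        missing = [n for n in NUCLEOTIDES if n not in letter_rows]
        if missing:
            raise PwmError(
                f"record {len(pwms) + 1} ({record_id}) before line {lineno}: "
                f"missing rows for {','.join(missing)}")
        widths = {len(v) for v in letter_rows.values()}
        if len(widths) != 1:
            raise PwmError(
                f"record {len(pwms) + 1} ({record_id}): unequal row lengths")
        rows = np.array([letter_rows[n] for n in NUCLEOTIDES]).T
        pwms.append(_finish_matrix(
            record_id or f"record{len(pwms) + 1}", names, rows,
            pseudocount, background, dialect, len(pwms) + 1,
            as_probabilities=(dialect == "uniprobe")))
        record_id, names, letter_rows = None, [], {}

    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            parts = line[1:].split(None, 1)
            record_id = parts[0] if parts else f"record{len(pwms) + 1}"
            if len(parts) > 1:
                names = [n for n in re.split(r"[;\s]+", parts[1]) if n]
            continue
        m = re.match(r"^([ACGTacgt])\s*[:|]?\s*\[?\s*(.*?)\s*\]?\s*$", line)
        if m:
            letter = m.group(1).upper()
            if letter in letter_rows:
                # UNIPROBE files may lack '>' headers: a repeated letter row
                # starts a new record.
                flush(lineno)
            try:
                letter_rows[letter] = [float(x) for x in m.group(2).split()]
            except ValueError:
                raise PwmError(
                    f"record {len(pwms) + 1}: malformed matrix row at line "
                    f"{lineno}: {line!r}") from None
        elif dialect == "uniprobe" and not letter_rows:
            record_id = line.split()[0]  # bare identifier line
        else:
            raise PwmError(
                f"record {len(pwms) + 1}: unexpected line {lineno}: {line!r}")
    flush(lineno="EOF")
    return pwms


def _parse_generic(stream, pseudocount, background):
    pwms = []
    record_id = None
    names: list[str] = []
    rows: list[list[float]] = []

    def flush():
        nonlocal record_id, names, rows
        if record_id is None and not rows:
            return
        pwms.append(_finish_matrix(
            record_id or f"record{len(pwms) + 1}", names, rows,
            pseudocount, background, "generic", len(pwms) + 1))
        record_id, names, rows = None, [], []

    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            record_id = parts[0] if parts else None
            if len(parts) > 1:
                names = [n for n in re.split(r"[;\s]+", parts[1]) if n]
            continue
        fields = line.split()
        if len(fields) != 4:
            raise PwmError(
                f"record {len(pwms) + 1}: expected 4 columns (A C G T) at "
                f"line {lineno}: {line!r}")
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            raise PwmError(
                f"record {len(pwms) + 1}: non-numeric value at line "
                f"{lineno}: {line!r}") from None
    flush()
    return pwms


def _sniff_dialect(text: str) -> str:
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line[:2] in ("ID", "AC", "P0", "PO") and (
            len(line) == 2 or line[2] in " \t"
        ) or line.startswith("VV") or line.startswith("XX"):
            return "transfac"
        if line.startswith(">"):
            # JASPAR if letter rows follow, generic otherwise.
            for nxt in text.splitlines()[text.splitlines().index(raw) + 1:]:
                s = nxt.strip()
                if not s:
                    continue
                return "jaspar" if re.match(r"^[ACGTacgt]\s*[:|\[\s]", s) else "generic"
            return "generic"
        if re.match(r"^[ACGTacgt]\s*:", line):
            return "uniprobe"
        return "uniprobe" if re.match(r"^\S+$", line) else "generic"
    return "generic"


def parse_pwm_collection(
    source,
    dialect: str = "auto",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: BackgroundModel = UNIFORM_BG,
) -> list[PositionWeightMatrix]:
    """Parse a motif collection from a stream or string.

    ``dialect`` is one of ``transfac``, ``jaspar``, ``uniprobe``, ``generic``
    or ``auto`` (sniffed from the first lines).  Count matrices are converted
    with :func:`counts_to_probabilities`; UNIPROBE probability matrices are
    rescaled to :data:`PROBABILITY_SCALE` observations per column before the
    same rule, which both renormalizes rounded columns and floors zeros.
    """
    stream = _as_stream(source)
    text = stream.read()
    if dialect == "auto":
        dialect = _sniff_dialect(text)
    stream = io.StringIO(text)
    if dialect == "transfac":
        return _parse_transfac(stream, pseudocount, background)
    if dialect in ("jaspar", "uniprobe"):
        return _parse_letter_rows(stream, dialect, pseudocount, background)
    if dialect == "generic":
        return _parse_generic(stream, pseudocount, background)
    raise PwmError(f"unknown PWM dialect: {dialect!r}")


def write_pwm_collection(pwms, stream, dialect: str = "generic") -> None:
    """Write matrices as probabilities in the generic or JASPAR dialect.

    Probabilities are written with enough digits that a write-then-parse round
    trip (with pseudocount 0) reproduces them to 1e-9.
    """
    if dialect == "jaspar":
        for pwm in pwms:
            header = " ".join([pwm.id] + list(pwm.names))
            stream.write(f">{header}\n")
            for i, n in enumerate(NUCLEOTIDES):
                vals = " ".join(f"{x:.12g}" for x in pwm.probs[:, i])
                stream.write(f"{n} [ {vals} ]\n")
    elif dialect == "generic":
        for pwm in pwms:
            header = " ".join([pwm.id] + list(pwm.names))
            stream.write(f">{header}\n")
            for row in pwm.probs:
                stream.write("\t".join(f"{x:.12g}" for x in row) + "\n")
    else:
        raise PwmError(f"unsupported output dialect: {dialect!r}")
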