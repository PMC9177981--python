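"""Position weight matrices: parsing, log-odds scoring, built-in GRE/CRE models.

Matrices are probability matrices over {A, C, G, T} with a background
distribution (uniform 0.25 by default).  Log-odds are natural-log ratios
ln(p/bg) after applying a small pseudocount, so a motif's consensus score
is the maximum attainable log-odds of any sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class PWM:
    """A 4 x L probability matrix (rows A, C, G, T)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1e-3
    threshold: float | None = None  # log-odds threshold from the motif file

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if self.probs.shape[1] < 4:
            raise ValueError("PWM must be at least 4 columns long")
        colsums = self.probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if self.consensus_score <= 0:
            raise ValueError("consensus log-odds must be positive")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L natural-log odds matrix with pseudocount regularization."""
        p = (self.probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log(p / self.background[:, None])

    @property
    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=0))

    @property
    def default_threshold(self) -> float:
        """File-supplied log-odds threshold, else 0.7 x consensus score."""
        if self.threshold is not None:
            return self.threshold
        return 0.7 * self.consensus_score

    def reverse_complement_matrix(self) -> np.ndarray:
        """Log-odds matrix scoring the minus strand at the same positions."""
        return self.log_odds[::-1, ::-1]

    def score_sequence(self, seq: str) -> float:
        """Log-odds of one sequence of exactly motif length (plus strand)."""
        if len(seq) != self.length:
            raise ValueError("sequence length must equal motif length")
        lom = self.log_odds
        return float(
            sum(lom[_BASE_INDEX[b], i] for i, b in enumerate(seq.upper()))
        )


def read_pwm(path) -> list[PWM]:
    """Read HOMER-style motif text: '>consensus name [logodds_threshold]'
    header then one row of 4 probabilities per motif position."""
    motifs = []
    name, threshold, rows = None, None, []

    def flush():
        if name is not None:
            motifs.append(
                PWM(name=name, probs=np.array(rows).T, threshold=threshold)
            )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                name = fields[1] if len(fields) > 1 else fields[0]
                threshold = float(fields[2]) if len(fields) > 2 else None
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError("PWM rows must have 4 probabilities")
                rows.append(vals)
    flush()
    return motifs


def write_pwm(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            header = f">{pwm.consensus}\t{pwm.name}"
            if pwm.threshold is not None:
                header += f"\t{pwm.threshold:.6g}"
            fh.write(header + "\n")
            for row in pwm.probs.T:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def _column(base: str, p_dom: float, second: str | None = None,
            p_second: float | None = None) -> np.ndarray:
    """One PWM column.  'N' is uniform.  A 'tolerant' column names a second
    base carrying most of the non-consensus probability, which makes the
    cost of a single consensus->second substitution small while keeping the
    other two bases strongly penalized."""
    col = np.empty(4)
    if base == "N":
        col[:] = 0.25
        return col
    if second is None:
        col[:] = (1.0 - p_dom) / 3.0
    else:
        rest = (1.0 - p_dom - p_second) / 2.0
        col[:] = rest
        col[_BASE_INDEX[second]] = p_second
    col[_BASE_INDEX[base]] = p_dom
    return col


def gre_pwm() -> PWM:
    """Glucocorticoid response element: two pseudo-palindromic half-sites
    around a 3-bp uninformative spacer.  Four tolerant positions give the
    motif a graded strength scale, mirroring the biological range from
    consensus-like 'strong' GREs to degenerate 'weak' ones."""
    cols = [
        _column("G", 0.94),
        _column("G", 0.94),
        _column("T", 0.94),
        _column("A", 0.60, "G", 0.28),   # tolerant
        _column("C", 0.94),
        _column("A", 0.60, "T", 0.28),   # tolerant
        _column("N", 0.0),
        _column("N", 0.0),
        _column("N", 0.0),
        _column("T", 0.60, "C", 0.28),   # tolerant
        _column("G", 0.94),
        _column("T", 0.60, "A", 0.28),   # tolerant
        _column("T", 0.94),
        _column("C", 0.94),
        _column("T", 0.94),
    ]
    return PWM("GRE", np.column_stack(cols))


def cre_pwm() -> PWM:
    """cAMP response element (CREB).  The consensus TGACGTCA is palindromic,
    but the column makeup is asymmetric (tolerant positions only in the
    3' half) so that degraded instances score differently on the two
    strands and planted orientations stay recoverable.  Being short, the
    motif carries an explicit log-odds threshold (as distributed motif
    files do) instead of relying on the 0.7 x consensus default."""
    cols = [
        _column("T", 0.97),
        _column("G", 0.97),
        _column("A", 0.97),
        _column("C", 0.97),
        _column("G", 0.97),
        _column("T", 0.60, "C", 0.28),   # tolerant
        _column("C", 0.60, "A", 0.28),   # tolerant
        _column("A", 0.60, "G", 0.28),   # tolerant
    ]
    return PWM("CRE", np.column_stack(cols), threshold=8.6)
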