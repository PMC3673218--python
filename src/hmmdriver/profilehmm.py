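"""Profile hidden Markov models and the residue -> match-state machinery.

A profile HMM models a protein family as a chain of *match states*, each
carrying an emission distribution over the 20 amino acids. A substitution
is scorable only when its residue position maps onto a match state of a
domain model assigned to the protein with a significant e-value
(<= 0.01 by default). When several models cover the same position, the
most informative one is chosen: the model whose match-state emission
vector has the largest Kullback-Leibler divergence (information gain, in
nats) from a background amino acid composition.

The module reads and writes profiles in the HMMER3 ASCII format, where
emissions are stored as negative natural-log scores (``-ln p``, with
``*`` denoting probability zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS
from .errors import DimensionError, FormatError, ParseError, RegistryError, ValidationError

_PROB_TOL = 1e-6

#: UniProtKB/Swiss-Prot amino acid composition (per-residue frequencies, %),
#: used as the default null model when a profile carries no COMPO line and no
#: explicit background is supplied. Overridable everywhere a background is
#: accepted.
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.64, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}


class ModelSource(Enum):
    SUPERFAMILY = "SUPERFAMILY"
    PFAM_A = "PFAM_A"
    PFAM_B = "PFAM_B"
    AB_INITIO = "AB_INITIO"


def _validate_composition(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_AMINO_ACIDS,):
        raise DimensionError(f"{what}: expected {N_AMINO_ACIDS} probabilities, got shape {p.shape}")
    if not np.all(p > 0):
        raise ValidationError(f"{what}: all probabilities must be strictly positive")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValidationError(f"{what}: probabilities sum to {p.sum():.8f}, not 1 within {_PROB_TOL}")
    return p


@dataclass(frozen=True)
class BackgroundComposition:
    """A null amino acid composition (e.g. SwissProt/TrEMBL frequencies)."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", _validate_composition(self.probabilities, "background")
        )

    @classmethod
    def from_mapping(cls, freqs: Mapping[str, float]) -> "BackgroundComposition":
        missing = set(AMINO_ACIDS) - set(freqs)
        if missing:
            raise ValidationError(f"background composition missing residues: {sorted(missing)}")
        v = np.array([float(freqs[a]) for a in AMINO_ACIDS])
        return cls(v / v.sum())

    @classmethod
    def default(cls) -> "BackgroundComposition":
        return cls.from_mapping(SWISSPROT_COMPOSITION)


@dataclass(frozen=True)
class ProfileHMM:
    """A profile HMM reduced to what scoring needs: match-state emissions.

    Parameters
    ----------
    model_id : str
        Model name (``NAME`` field of the HMMER3 file).
    source : ModelSource
        Provenance of the model (domain library or ab-initio build).
    emissions : (length, 20) ndarray
        Per-match-state amino acid emission probabilities, rows summing
        to 1; match states are 1-based externally.
    background : (20,) ndarray
        The model's null composition (``COMPO`` line when present).
    """

    model_id: str
    source: ModelSource
    emissions: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.emissions, dtype=float)
        if e.ndim != 2 or e.shape[1] != N_AMINO_ACIDS or e.shape[0] < 1:
            raise DimensionError(f"emissions must be (length>=1, 20), got {e.shape}")
        for i, row in enumerate(e, start=1):
            _validate_composition(row, f"match state {i} emissions")
        object.__setattr__(self, "emissions", e)
        object.__setattr__(
            self, "background", _validate_composition(self.background, "model background")
        )

    @property
    def length(self) -> int:
        """Number of match states."""
        return self.emissions.shape[0]

    def emission_vector(self, match_state: int) -> np.ndarray:
        """Emission distribution at a 1-based match state."""
        if not 1 <= match_state <= self.length:
            raise ValidationError(
                f"match state {match_state} outside [1, {self.length}] for {self.model_id}"
            )
        return self.emissions[match_state - 1]

    def emission(self, match_state: int, residue: str) -> float:
        """Probability of `residue` at a 1-based match state."""
        from .alphabet import AA_INDEX, check_residue

        return float(self.emission_vector(match_state)[AA_INDEX[check_residue(residue)]])


@dataclass(frozen=True)
class DomainAssignment:
    """A protein <-> model alignment, with e-value and an M/I/D ops string.

    The ops string describes the alignment column by column starting at
    (`seq_start`, `hmm_start`), both 1-based: ``M`` consumes one residue
    and one match state, ``I`` one residue only (insert), ``D`` one match
    state only (deletion).
    """

    protein_id: str
    model_id: str
    e_value: float
    seq_start: int
    hmm_start: int
    ops: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"e_value must be >= 0, got {self.e_value}")
        if not self.ops:
            raise ValidationError("ops string must be non-empty")
        bad = set(self.ops) - set("MID")
        if bad:
            raise ValidationError(f"ops contains letters outside M/I/D: {sorted(bad)}")
        if self.seq_start < 1 or self.hmm_start < 1:
            raise ValidationError("seq_start and hmm_start are 1-based and must be >= 1")

    @property
    def hmm_end(self) -> int:
        """Last match state touched by the alignment (1-based, closed)."""
        return self.hmm_start + sum(1 for c in self.ops if c in "MD") - 1

    def check_against(self, model: ProfileHMM) -> None:
        if self.hmm_end > model.length:
            raise ValidationError(
                f"assignment {self.protein_id}->{self.model_id} runs to match state "
                f"{self.hmm_end} but the model has only {model.length}"
            )


def map_position_to_match_state(a: DomainAssignment, position: int) -> int | None:
    """Map a 1-based residue position onto the model's match state, or None.

    Returns None when the residue falls in an insert column or outside the
    aligned span: such positions are not scorable under this assignment.
    """
    if position < 1:
        raise ValidationError(f"position is 1-based; got {position}")
    seq = a.seq_start
    hmm = a.hmm_start
    for op in a.ops:
        if op == "M":
            if seq == position:
                return hmm
            seq += 1
            hmm += 1
        elif op == "I":
            if seq == position:
                return None
            seq += 1
        else:  # D
            hmm += 1
        if seq > position:
            return None
    return None


def kl_information_gain(p: Sequence[float] | np.ndarray, q: "BackgroundComposition | np.ndarray") -> float:
    """Kullback-Leibler divergence sum(p * ln(p/q)) in nats.

    Non-negative; zero iff the two compositions are identical. Natural
    logs are used throughout, matching the natural-log scale of the
    substitution score.
    """
    qv = q.probabilities if isinstance(q, BackgroundComposition) else np.asarray(q, dtype=float)
    pv = np.asarray(p, dtype=float)
    if pv.shape != qv.shape:
        raise DimensionError(f"alphabet mismatch: p has shape {pv.shape}, q has {qv.shape}")
    return float(np.sum(pv * np.log(pv / qv)))


class ModelRegistry:
    """Resolves model_id -> ProfileHMM; raises RegistryError on a miss."""

    def __init__(self, models: Iterable[ProfileHMM] = ()) -> None:
        self._models: dict[str, ProfileHMM] = {}
        for m in models:
            self.add(m)

    def add(self, model: ProfileHMM) -> None:
        if model.model_id in self._models:
            raise ValidationError(f"duplicate model id {model.model_id!r}")
        self._models[model.model_id] = model

    def get(self, model_id: str) -> ProfileHMM:
        try:
            return self._models[model_id]
        except KeyError:
            raise RegistryError(f"unknown model id {model_id!r}") from None

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._models

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self):
        return iter(self._models.values())

    @classmethod
    def from_directory(cls, directory: str | Path, source: ModelSource = ModelSource.AB_INITIO) -> "ModelRegistry":
        """Load every ``*.hmm`` file under `directory` (non-recursive)."""
        reg = cls()
        for path in sorted(Path(directory).glob("*.hmm")):
            reg.add(read_hmmer3_profile(path, source=source))
        return reg


def select_model(
    assignments: Sequence[DomainAssignment],
    position: int,
    registry: ModelRegistry,
    bg: BackgroundComposition,
    e_max: float = 0.01,
    positional_kl: bool = True,
) -> tuple[ProfileHMM, int] | None:
    """Pick the most informative significant model covering `position`.

    Candidates must have e-value <= `e_max` and map `position` onto a
    match state. Among survivors the model with the largest KL
    information gain against `bg` wins — computed at the mapped match
    state by default (the score itself is positional), or as the mean KL
    over all match states when ``positional_kl=False``. Ties break on
    (lower e-value, lexicographic model_id) for determinism.

    Returns ``(model, match_state)`` or None when no assignment survives.
    """
    best: tuple[float, float, str] | None = None
    best_pair: tuple[ProfileHMM, int] | None = None
    for a in assignments:
        if a.e_value > e_max:
            continue
        ms = map_position_to_match_state(a, position)
        if ms is None:
            continue
        model = registry.get(a.model_id)
        if positional_kl:
            gain = kl_information_gain(model.emission_vector(ms), bg)
        else:
            gain = float(
                np.mean([kl_information_gain(row, bg) for row in model.emissions])
            )
        # maximise gain; ties -> lower e-value, then lexicographic model_id
        key = (-gain, a.e_value, model.model_id)
        if best is None or key < best:
            best = key
            best_pair = (model, ms)
    return best_pair


# ---------------------------------------------------------------------------
# HMMER3 ASCII I/O
# ---------------------------------------------------------------------------

_LOG_INF = "*"  # the format's marker for -ln(0)


def _score_to_prob(token: str, context: str) -> float:
    if token == _LOG_INF:
        return 0.0
    try:
        score = float(token)
    except ValueError:
        raise ParseError(f"{context}: unparseable score token {token!r}") from None
    if not math.isfinite(score):
        raise ParseError(f"{context}: non-finite score token {token!r}")
    return math.exp(-score)


def _prob_to_score(p: float) -> str:
    # 10 decimal places keeps the probability round-trip well under 1e-9
    if p <= 0.0:
        return f"{_LOG_INF:>13s}"
    return f"{-math.log(p):13.10f}"


def read_hmmer3_profile(
    path: str | Path,
    source: ModelSource = ModelSource.AB_INITIO,
    default_background: BackgroundComposition | None = None,
) -> ProfileHMM:
    """Read a profile from a HMMER3 ASCII file.

    Match emissions are converted from negative-natural-log scores to
    probabilities. The model background is taken from the ``COMPO`` line
    when present, else from `default_background` (SwissProt composition
    if not given). Only the first model in the file is read.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise FormatError(f"{path}: missing HMMER3 format declaration in header")

    name: str | None = None
    length: int | None = None
    alph: str | None = None
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "NAME":
            name = parts[1] if len(parts) > 1 else None
        elif key == "LENG":
            try:
                length = int(parts[1])
            except (IndexError, ValueError):
                raise FormatError(f"{path}: malformed LENG line {lines[i]!r}") from None
        elif key == "ALPH":
            alph = parts[1].lower() if len(parts) > 1 else None
        elif key == "HMM":
            symbols = parts[1:]
            if symbols != list(AMINO_ACIDS):
                raise FormatError(
                    f"{path}: HMM symbol line does not list the 20 amino acids in "
                    f"HMMER order; got {symbols}"
                )
            break
        i += 1
    else:
        raise FormatError(f"{path}: no HMM line found")

    if name is None or length is None:
        raise FormatError(f"{path}: header missing NAME or LENG")
    if alph != "amino":
        raise FormatError(f"{path}: alphabet is {alph!r}, expected 'amino'")
    if length < 1:
        raise ValidationError(f"{path}: LENG must be >= 1, got {length}")

    i += 2  # skip the transition-header line
    background: np.ndarray | None = None
    parts = lines[i].split()
    if parts and parts[0] == "COMPO":
        background = np.array(
            [_score_to_prob(t, f"{path} COMPO") for t in parts[1 : 1 + N_AMINO_ACIDS]]
        )
        i += 1
    i += 2  # node-0 insert emissions and transitions

    emissions = np.empty((length, N_AMINO_ACIDS))
    for k in range(1, length + 1):
        parts = lines[i].split()
        if not parts or parts[0] != str(k):
            raise FormatError(f"{path}: expected node {k} match-emission line, got {lines[i]!r}")
        tokens = parts[1 : 1 + N_AMINO_ACIDS]
        if len(tokens) < N_AMINO_ACIDS:
            raise FormatError(f"{path}: node {k} has {len(tokens)} emission scores, expected 20")
        emissions[k - 1] = [_score_to_prob(t, f"{path} node {k}") for t in tokens]
        i += 3  # match line + insert line + transition line

    if background is None:
        bg = default_background or BackgroundComposition.default()
        background = bg.probabilities

    return ProfileHMM(model_id=name, source=source, emissions=emissions, background=background)


def write_hmmer3_profile(model: ProfileHMM, path: str | Path) -> None:
    """Write a minimal but valid HMMER3/f ASCII file for `model`.

    Intended for fixtures: insert emissions are set to the model
    background and transitions to generic profile values; match
    emissions and COMPO round-trip exactly (within float formatting).
    """
    path = Path(path)
    bg_scores = "  ".join(_prob_to_score(p) for p in model.background)
    with path.open("w", newline="\n") as fh:
        fh.write("HMMER3/f [3.4 | hmmdriver fixture writer]\n")
        fh.write(f"NAME  {model.model_id}\n")
        fh.write(f"LENG  {model.length}\n")
        fh.write("ALPH  amino\n")
        fh.write("RF    no\nMM    no\nCONS  no\nCS    no\nMAP   no\n")
        fh.write("HMM     " + "        ".join(AMINO_ACIDS) + "   \n")
        fh.write("        " + "     ".join(["m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d"]) + "\n")
        fh.write(f"  COMPO  {bg_scores}\n")
        fh.write(f"         {bg_scores}\n")
        # node 0 transitions: B->M1 dominant, D0 unreachable
        fh.write("          0.10536  2.99573  2.99573  0.69315  0.69315  0.00000        *\n")
        for k in range(1, model.length + 1):
            scores = "  ".join(_prob_to_score(p) for p in model.emissions[k - 1])
            fh.write(f"{k:>7d}  {scores}      - - - - -\n")
            fh.write(f"         {bg_scores}\n")
            if k < model.length:
                fh.write("          0.10536  2.99573  2.99573  0.69315  0.69315  0.69315  0.69315\n")
            else:
                fh.write("          0.05129  2.99573        *  0.69315  0.69315  0.00000        *\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# Domain assignment TSV I/O
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = ("protein_id", "model_id", "e_value", "seq_start", "hmm_start", "ops")


class AssignmentStore:
    """Domain assignments indexed by protein id."""

    def __init__(self, assignments: Iterable[DomainAssignment] = ()) -> None:
        self._by_protein: dict[str, list[DomainAssignment]] = {}
        for a in assignments:
            self._by_protein.setdefault(a.protein_id, []).append(a)

    def for_protein(self, protein_id: str) -> list[DomainAssignment]:
        return self._by_protein.get(protein_id, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_protein.values())

    def __iter__(self):
        for pid in self._by_protein:
            yield from self._by_protein[pid]

    @property
    def protein_ids(self) -> list[str]:
        return list(self._by_protein)


def read_assignments_tsv(path: str | Path) -> AssignmentStore:
    """Read a domain-assignment table (one alignment per row).

    Columns: protein_id, model_id, e_value, seq_start, hmm_start, ops.
    Lines starting with ``#`` are comments; a header row is required.
    """
    path = Path(path)
    assignments = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != ASSIGNMENT_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {ASSIGNMENT_COLUMNS}, got {tuple(header)}"
                    )
                continue
            if len(fields) != len(ASSIGNMENT_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(ASSIGNMENT_COLUMNS)} fields")
            rec = dict(zip(ASSIGNMENT_COLUMNS, fields))
            try:
                assignments.append(
                    DomainAssignment(
                        protein_id=rec["protein_id"],
                        model_id=rec["model_id"],
                        e_value=float(rec["e_value"]),
                        seq_start=int(rec["seq_start"]),
                        hmm_start=int(rec["hmm_start"]),
                        ops=rec["ops"],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return AssignmentStore(assignments)


def write_assignments_tsv(assignments: Iterable[DomainAssignment], path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write(
                f"{a.protein_id}\t{a.model_id}\t{a.e_value:g}\t{a.seq_start}\t{a.hmm_start}\t{a.ops}\n"
            )
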