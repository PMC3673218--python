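"""Cancer-specific pathogenicity weights.

Each profile HMM gets a pair of weights: W_c, the relative frequency of
cancer-associated substitutions mapping onto it, and W_p, the relative
frequency of putatively neutral polymorphisms. "Relative frequency"
means per-model count over the class's total mapped count, so each
class's weights sum to 1 across models (a ``raw`` mode exposing the
unnormalised counts is also available). A pseudo-count delta (default
1.0) is added to both weights at scoring time, not folded into the
stored frequencies, so tables stay interpretable.

For ab-initio models built from homologous-sequence alignments, the
weights aggregate over the member proteins that contributed to the
model rather than over domain assignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alphabet import check_residue
from .errors import (
    FormatError,
    HmmdriverError,
    ParseError,
    SynonymousInputError,
    ValidationError,
)
from .profilehmm import AssignmentStore, BackgroundComposition, ModelRegistry, select_model


class VariantLabel(Enum):
    CANCER = "CANCER"
    NEUTRAL = "NEUTRAL"


class WeightMode(Enum):
    RELATIVE = "relative"
    RAW = "raw"


_SUBSTITUTION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Parse ``R175H``-style notation into (wild_type, position, mutant).

    Rejects synonymous inputs (identical residues) and nonstandard
    letters; positions are 1-based.
    """
    m = _SUBSTITUTION_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse substitution {text!r} (expected e.g. 'R175H')")
    wt, pos, mut = check_residue(m.group(1)), int(m.group(2)), check_residue(m.group(3))
    if pos < 1:
        raise ParseError(f"substitution {text!r} has non-positive position")
    if wt == mut:
        raise SynonymousInputError(f"substitution {text!r} is synonymous (wild-type == mutant)")
    return wt, pos, mut


@dataclass(frozen=True)
class VariantRecord:
    """A labelled amino acid substitution on a protein."""

    protein_id: str
    wild_type: str
    position: int
    mutant: str
    label: VariantLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "wild_type", check_residue(self.wild_type))
        object.__setattr__(self, "mutant", check_residue(self.mutant))
        if self.wild_type == self.mutant:
            raise SynonymousInputError(
                f"{self.protein_id} {self.substitution}: wild-type equals mutant"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @property
    def substitution(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity without the label (used for de-duplication)."""
        return (self.protein_id, self.wild_type, self.position, self.mutant)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a labelled variant catalogue.

    Columns: protein_id, substitution, label (CANCER | NEUTRAL).
    Duplicate records are collapsed to one; the same substitution
    carrying both labels is a validation error, not arbitrated.
    """
    path = Path(path)
    seen: dict[tuple, VariantRecord] = {}
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:3] != ["protein_id", "substitution", "label"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected columns protein_id, substitution, label"
                    )
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            pid, sub, label_text = fields[0], fields[1], fields[2]
            try:
                wt, pos, mut = parse_substitution(sub)
                label = VariantLabel(label_text.strip().upper())
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            rec = VariantRecord(pid, wt, pos, mut, label)
            prev = seen.get(rec.key)
            if prev is not None:
                if prev.label != rec.label:
                    raise ValidationError(
                        f"{path}:{lineno}: {pid} {sub} appears with conflicting labels "
                        f"{prev.label.value} and {rec.label.value}"
                    )
                continue  # exact duplicate: counted once
            seen[rec.key] = rec
    return list(seen.values())


def write_variants_tsv(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("protein_id\tsubstitution\tlabel\n")
        for v in variants:
            fh.write(f"{v.protein_id}\t{v.substitution}\t{v.label.value}\n")


def dedupe_variants(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicates; conflicting labels on one substitution raise."""
    seen: dict[tuple, VariantRecord] = {}
    for v in variants:
        prev = seen.get(v.key)
        if prev is None:
            seen[v.key] = v
        elif prev.label != v.label:
            raise ValidationError(
                f"{v.protein_id} {v.substitution} carries conflicting labels"
            )
    return list(seen.values())


def assign_variants_to_models(
    variants: Sequence[VariantRecord],
    assignments: AssignmentStore,
    registry: ModelRegistry,
    bg: BackgroundComposition,
    e_max: float = 0.01,
) -> dict[VariantRecord, str | None]:
    """Route each variant through model selection at its position.

    Variants on uncovered proteins or positions map to None.
    """
    mapped: dict[VariantRecord, str | None] = {}
    for v in variants:
        hit = select_model(assignments.for_protein(v.protein_id), v.position, registry, bg, e_max)
        mapped[v] = hit[0].model_id if hit is not None else None
    return mapped


@dataclass(frozen=True)
class WeightRow:
    model_id: str
    cancer_count: int
    neutral_count: int
    w_c: float
    w_p: float


@dataclass(frozen=True)
class PathogenicityWeightTable:
    """Per-model cancer (W_c) and neutral (W_p) weights.

    In ``relative`` mode W_c/W_p are per-model counts divided by the
    class totals, so each class sums to 1 over models with mapped
    variants; in ``raw`` mode they are the counts themselves. The
    pseudo-count delta is stored here and applied by the scorer as
    (W + delta).
    """

    rows: Mapping[str, WeightRow]
    total_cancer: int
    total_neutral: int
    pseudo_count: float = 1.0
    weight_mode: WeightMode = WeightMode.RELATIVE

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValidationError(f"pseudo_count must be > 0, got {self.pseudo_count}")

    def weights_for(self, model_id: str) -> tuple[float, float]:
        """(w_c, w_p) for a model; absent rows contribute (0, 0)."""
        row = self.rows.get(model_id)
        return (row.w_c, row.w_p) if row is not None else (0.0, 0.0)

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)


def _make_table(
    counts: Mapping[str, tuple[int, int]],
    total_cancer: int,
    total_neutral: int,
    pseudo_count: float,
    weight_mode: WeightMode,
) -> PathogenicityWeightTable:
    rows = {}
    for model_id in sorted(counts):
        c, n = counts[model_id]
        if weight_mode is WeightMode.RELATIVE:
            w_c = c / total_cancer if total_cancer else 0.0
            w_p = n / total_neutral if total_neutral else 0.0
        else:
            w_c, w_p = float(c), float(n)
        rows[model_id] = WeightRow(model_id, c, n, w_c, w_p)
    return PathogenicityWeightTable(
        rows=rows,
        total_cancer=total_cancer,
        total_neutral=total_neutral,
        pseudo_count=pseudo_count,
        weight_mode=weight_mode,
    )


class WeightTableBuilder:
    """Builds weight tables from a variant -> model mapping.

    Keeps the mapping so cross-validation can rebuild tables with
    held-out variants excluded (single-variant exclusion by default;
    model-level exclusion available for a stricter leave-out scope).
    """

    def __init__(
        self,
        mapped: Mapping[VariantRecord, str | None],
        pseudo_count: float = 1.0,
        weight_mode: WeightMode = WeightMode.RELATIVE,
    ) -> None:
        if not mapped:
            raise ValidationError("empty variant->model mapping")
        self.mapped = dict(mapped)
        self.pseudo_count = pseudo_count
        self.weight_mode = weight_mode

    def build(self, exclude: Iterable[VariantRecord] = ()) -> PathogenicityWeightTable:
        excluded = set(exclude)
        unknown = excluded - set(self.mapped)
        if unknown:
            raise HmmdriverError(
                f"{len(unknown)} held-out variant(s) were not part of the construction input"
            )
        counts: dict[str, list[int]] = {}
        total_c = total_n = 0
        for v, model_id in self.mapped.items():
            if v in excluded or model_id is None:
                continue
            c = counts.setdefault(model_id, [0, 0])
            if v.label is VariantLabel.CANCER:
                c[0] += 1
                total_c += 1
            else:
                c[1] += 1
                total_n += 1
        if total_c == 0 and total_n == 0:
            raise ValidationError(
                "no variants mapped onto any model in either class; cannot build a weight table"
            )
        return _make_table(
            {m: (c, n) for m, (c, n) in counts.items()},
            total_c,
            total_n,
            self.pseudo_count,
            self.weight_mode,
        )

    def exclude_variant(self, held_out: VariantRecord) -> PathogenicityWeightTable:
        """Table rebuilt without one variant (leave-one-out semantics)."""
        return self.build(exclude=[held_out])


def compute_weight_table(
    mapped: Mapping[VariantRecord, str | None],
    pseudo_count: float = 1.0,
    weight_mode: WeightMode = WeightMode.RELATIVE,
) -> PathogenicityWeightTable:
    """One-shot table construction from a variant -> model mapping."""
    return WeightTableBuilder(mapped, pseudo_count, weight_mode).build()


# ---------------------------------------------------------------------------
# Ab-initio (outside-domain) weighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceMembership:
    """Proteins whose sequences contributed to an ab-initio model."""

    model_id: str
    member_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_protein_ids", frozenset(self.member_protein_ids))
        if not self.member_protein_ids:
            raise ValidationError(f"{self.model_id}: member protein set must be non-empty")


def weights_for_ab_initio_model(
    membership: SequenceMembership,
    variants: Sequence[VariantRecord],
    pseudo_count: float = 1.0,
    weight_mode: WeightMode = WeightMode.RELATIVE,
) -> WeightRow:
    """Weight row for a homology-built model, aggregated over members.

    Counts every labelled variant whose protein contributed to the
    model; relative frequencies use the same dataset totals as the
    domain-based table so the two weighting schemes are commensurable.
    """
    variants = dedupe_variants(variants)
    total_c = sum(1 for v in variants if v.label is VariantLabel.CANCER)
    total_n = sum(1 for v in variants if v.label is VariantLabel.NEUTRAL)
    c = sum(
        1
        for v in variants
        if v.label is VariantLabel.CANCER and v.protein_id in membership.member_protein_ids
    )
    n = sum(
        1
        for v in variants
        if v.label is VariantLabel.NEUTRAL and v.protein_id in membership.member_protein_ids
    )
    if weight_mode is WeightMode.RELATIVE:
        w_c = c / total_c if total_c else 0.0
        w_p = n / total_n if total_n else 0.0
    else:
        w_c, w_p = float(c), float(n)
    return WeightRow(membership.model_id, c, n, w_c, w_p)


def read_membership_tsv(path: str | Path) -> dict[str, SequenceMembership]:
    """Columns: model_id, comma-separated member protein ids."""
    path = Path(path)
    memberships: dict[str, SequenceMembership] = {}
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            members = frozenset(p for p in fields[1].split(",") if p)
            memberships[fields[0]] = SequenceMembership(fields[0], members)
    return memberships


def write_membership_tsv(memberships: Mapping[str, SequenceMembership], path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("model_id\tmember_protein_ids\n")
        for model_id in sorted(memberships):
            members = ",".join(sorted(memberships[model_id].member_protein_ids))
            fh.write(f"{model_id}\t{members}\n")


# ---------------------------------------------------------------------------
# Weight table TSV I/O
# ---------------------------------------------------------------------------


def write_weight_table_tsv(table: PathogenicityWeightTable, path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write(f"# total_cancer={table.total_cancer}\n")
        fh.write(f"# total_neutral={table.total_neutral}\n")
        fh.write(f"# pseudo_count={table.pseudo_count:g}\n")
        fh.write(f"# weight_mode={table.weight_mode.value}\n")
        fh.write("model_id\tcancer_count\tneutral_count\tw_c\tw_p\n")
        for model_id in sorted(table.rows):
            r = table.rows[model_id]
            fh.write(
                f"{r.model_id}\t{r.cancer_count}\t{r.neutral_count}\t"
                f"{r.w_c:.12g}\t{r.w_p:.12g}\n"
            )


def read_weight_table_tsv(path: str | Path) -> PathogenicityWeightTable:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: dict[str, WeightRow] = {}
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line.lstrip("# ").split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[:5] != ["model_id", "cancer_count", "neutral_count", "w_c", "w_p"]:
                    raise FormatError(f"{path}:{lineno}: unexpected weight-table header")
                header_seen = True
                continue
            try:
                rows[fields[0]] = WeightRow(
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]), float(fields[4])
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PathogenicityWeightTable(
        rows=rows,
        total_cancer=int(meta.get("total_cancer", 0)),
        total_neutral=int(meta.get("total_neutral", 0)),
        pseudo_count=float(meta.get("pseudo_count", 1.0)),
        weight_mode=WeightMode(meta.get("weight_mode", "relative")),
    )
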