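"""Self-contained synthetic fixtures with planted effect structure.

The generator emulates the statistical structure the classifier
assumes: conserved protein domains (profile HMMs with peaked emission
columns), cancer-associated substitutions that hit low-probability
residues at conserved positions of cancer-enriched models, and neutral
polymorphisms that swap between well-tolerated residues on
neutral-enriched models. Every planted quantity (per-model placement
frequencies, per-variant emissions and truth labels) is recorded in a
truth table so downstream modules can be tested for parameter recovery
without any external download.

Randomness is split into independent streams per artifact type, all
derived from the master seed, so regenerating one artifact class never
perturbs another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS
from .errors import ScenarioError
from .profilehmm import (
    AssignmentStore,
    BackgroundComposition,
    DomainAssignment,
    ModelRegistry,
    ModelSource,
    ProfileHMM,
    write_assignments_tsv,
    write_hmmer3_profile,
)
from .weights import (
    SequenceMembership,
    VariantLabel,
    VariantRecord,
    write_membership_tsv,
    write_variants_tsv,
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a planted-structure study.

    Defaults describe a small but realistic conserved-domain setting:
    4 domain families of 300 match states, half of them cancer-enriched,
    20 proteins, 500 substitutions per class. ``driver_emission_low``
    is the mutant-residue emission planted at driver positions;
    ``neutral_emission_high`` the mutant emission planted at tolerated
    positions. ``cancer_enrichment`` is the placement odds multiplier
    of cancer variants onto cancer-enriched models (0 = no enrichment).
    """

    seed: int = 7
    n_models: int = 4
    model_length: int = 300
    n_proteins: int = 20
    n_variants_per_class: int = 500
    driver_emission_low: float = 0.02
    neutral_emission_high: float = 0.30
    cancer_enrichment: float = 3.0
    concentration: float = 0.3  # Dirichlet concentration; low = conserved columns

    def __post_init__(self) -> None:
        for name in ("driver_emission_low", "neutral_emission_high"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ScenarioError(f"{name} must lie in (0,1), got {v}")
        for name in ("n_models", "model_length", "n_proteins", "n_variants_per_class"):
            if getattr(self, name) < 1:
                raise ScenarioError(f"{name} must be >= 1")
        if self.cancer_enrichment < 0:
            raise ScenarioError("cancer_enrichment must be >= 0")
        if self.driver_emission_low * N_AMINO_ACIDS > 1.0:
            raise ScenarioError(
                "driver_emission_low is too large to leave room for a dominant wild-type residue"
            )
        if self.driver_emission_low + self.neutral_emission_high >= 1.0:
            raise ScenarioError("planted emissions exceed a valid composition")
        if 2 * self.n_variants_per_class > self.n_models * self.model_length:
            raise ScenarioError(
                "not enough match-state columns to give every planted variant its own: "
                f"need {2 * self.n_variants_per_class}, have {self.n_models * self.model_length}"
            )


@dataclass
class ScenarioBundle:
    """Everything one synthetic study produces, in memory."""

    scenario: SyntheticScenario
    registry: ModelRegistry
    assignments: AssignmentStore
    variants: list[VariantRecord]
    memberships: dict[str, SequenceMembership]
    truth: dict


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("profiles", "assignments", "variants")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def _sample_column(rng: np.random.Generator, concentration: float) -> np.ndarray:
    # floor keeps every emission strictly positive, as the HMM format demands
    p = rng.dirichlet(np.full(N_AMINO_ACIDS, concentration))
    p = np.maximum(p, 1e-6)
    return p / p.sum()


def _plant_pair(
    column: np.ndarray, wt_idx: int, mut_idx: int, wt_target: float, mut_target: float
) -> np.ndarray:
    """Rescale a column so wt/mut residues hit the planted probabilities."""
    out = column.copy()
    others = np.ones(N_AMINO_ACIDS, dtype=bool)
    others[[wt_idx, mut_idx]] = False
    rest = out[others]
    out[wt_idx] = wt_target
    out[mut_idx] = mut_target
    out[others] = rest / rest.sum() * (1.0 - wt_target - mut_target)
    out = np.maximum(out, 1e-9)
    return out / out.sum()


def generate_scenario(scenario: SyntheticScenario = SyntheticScenario()) -> ScenarioBundle:
    """Generate profiles, assignments, labelled variants and the truth table.

    Deterministic given the scenario (including its seed). Models with
    even index are designated cancer-enriched; cancer variants land on
    them with odds multiplied by ``cancer_enrichment``, and vice versa
    for neutral variants. Driver substitutions are planted at columns
    where the mutant emission is at most ``driver_emission_low`` and
    the wild type is the column mode; neutral substitutions swap to a
    residue with emission ``neutral_emission_high``.
    """
    s = scenario
    rngs = _streams(s.seed)
    model_ids = [f"SYN{i:03d}" for i in range(s.n_models)]
    cancer_models = {m for i, m in enumerate(model_ids) if i % 2 == 0}

    # --- proteins tile the models; one significant assignment each
    protein_ids = [f"PROT{i:04d}" for i in range(s.n_proteins)]
    protein_model = {p: model_ids[i % s.n_models] for i, p in enumerate(protein_ids)}
    assignments = [
        DomainAssignment(
            protein_id=p,
            model_id=protein_model[p],
            e_value=1e-5,
            seq_start=1,
            hmm_start=1,
            ops="M" * s.model_length,
        )
        for p in protein_ids
    ]
    membership: dict[str, set[str]] = {m: set() for m in model_ids}
    for p, m in protein_model.items():
        membership[m].add(p)

    # --- emission columns, then planted variant structure
    prof_rng = rngs["profiles"]
    emissions = {
        m: np.vstack(
            [_sample_column(prof_rng, s.concentration) for _ in range(s.model_length)]
        )
        for m in model_ids
    }

    var_rng = rngs["variants"]

    def placement_probs(label: VariantLabel) -> np.ndarray:
        odds = np.ones(s.n_models)
        for i, m in enumerate(model_ids):
            enriched = (m in cancer_models) == (label is VariantLabel.CANCER)
            if enriched:
                odds[i] = 1.0 + s.cancer_enrichment
        return odds / odds.sum()

    planted_placement = {
        "CANCER": placement_probs(VariantLabel.CANCER).tolist(),
        "NEUTRAL": placement_probs(VariantLabel.NEUTRAL).tolist(),
    }

    proteins_by_model = {
        m: [p for p in protein_ids if protein_model[p] == m] for m in model_ids
    }

    variants: list[VariantRecord] = []
    truth_variants: list[dict] = []
    used_positions: dict[str, set[int]] = {m: set() for m in model_ids}

    def place(label: VariantLabel, count: int) -> None:
        probs = placement_probs(label)
        for _ in range(count):
            # spill over to models with free columns if the drawn one is full,
            # so every variant keeps its own planted column
            avail = np.array(
                [len(used_positions[m]) < s.model_length for m in model_ids], dtype=bool
            )
            p = np.where(avail, probs, 0.0)
            p = p / p.sum()
            m = model_ids[var_rng.choice(s.n_models, p=p)]
            protein = proteins_by_model[m][var_rng.integers(len(proteins_by_model[m]))]
            free = [c for c in range(s.model_length) if c not in used_positions[m]]
            col_idx = free[var_rng.integers(len(free))]
            used_positions[m].add(col_idx)
            column = emissions[m][col_idx]
            wt_idx = int(np.argmax(column))
            choices = [i for i in range(N_AMINO_ACIDS) if i != wt_idx]
            mut_idx = choices[var_rng.integers(len(choices))]
            # lognormal jitter spreads each class's score distribution so the
            # two overlap near the decision threshold instead of separating
            # perfectly: a small tail of drivers is only mildly deleterious
            # and a tail of neutral swaps is fairly damaging
            if label is VariantLabel.CANCER:
                wt_target = float(np.clip(0.60 * np.exp(var_rng.normal(0, 0.20)), 0.25, 0.90))
                mut_target = float(
                    np.clip(s.driver_emission_low * np.exp(var_rng.normal(0, 1.6)), 1e-4, 0.35)
                )
            else:
                wt_target = float(np.clip(0.40 * np.exp(var_rng.normal(0, 0.25)), 0.15, 0.60))
                mut_target = float(
                    np.clip(s.neutral_emission_high * np.exp(var_rng.normal(0, 0.45)), 0.03, 0.39)
                )
            mut_target = min(mut_target, 0.97 - wt_target)
            emissions[m][col_idx] = _plant_pair(column, wt_idx, mut_idx, wt_target, mut_target)
            position = col_idx + 1  # seq_start = hmm_start = 1, all-M ops
            rec = VariantRecord(
                protein_id=protein,
                wild_type=AMINO_ACIDS[wt_idx],
                position=position,
                mutant=AMINO_ACIDS[mut_idx],
                label=label,
            )
            variants.append(rec)
            truth_variants.append(
                {
                    "protein_id": protein,
                    "substitution": rec.substitution,
                    "label": label.value,
                    "model_id": m,
                    "match_state": position,
                    "p_w": float(emissions[m][col_idx][wt_idx]),
                    "p_m": float(emissions[m][col_idx][mut_idx]),
                }
            )

    place(VariantLabel.CANCER, s.n_variants_per_class)
    place(VariantLabel.NEUTRAL, s.n_variants_per_class)

    bg = BackgroundComposition.default()
    registry = ModelRegistry(
        ProfileHMM(
            model_id=m,
            source=ModelSource.AB_INITIO,
            emissions=emissions[m],
            background=bg.probabilities,
        )
        for m in model_ids
    )

    # planted per-model relative placement frequencies (the quantity the
    # weights module should recover from the catalogues)
    planted_wc = {m: 0 for m in model_ids}
    planted_wp = {m: 0 for m in model_ids}
    for t in truth_variants:
        if t["label"] == "CANCER":
            planted_wc[t["model_id"]] += 1
        else:
            planted_wp[t["model_id"]] += 1
    n = s.n_variants_per_class
    truth = {
        "scenario": asdict(s),
        "model_ids": model_ids,
        "cancer_models": sorted(cancer_models),
        "planted_placement_probs": planted_placement,
        "realized_w_c": {m: planted_wc[m] / n for m in model_ids},
        "realized_w_p": {m: planted_wp[m] / n for m in model_ids},
        "variants": truth_variants,
    }

    memberships = {
        m: SequenceMembership(m, frozenset(members))
        for m, members in membership.items()
        if members
    }
    return ScenarioBundle(
        scenario=s,
        registry=registry,
        assignments=AssignmentStore(assignments),
        variants=variants,
        memberships=memberships,
        truth=truth,
    )


def write_fixture_bundle(bundle: ScenarioBundle, directory: str | Path) -> dict:
    """Write the bundle as plain-text files; returns a hash manifest.

    Emits one ``<model_id>.hmm`` per profile, ``assignments.tsv``,
    ``variants.tsv``, ``membership.tsv`` and ``truth.json``. The
    manifest maps file names to SHA256 hashes, so any change in a
    generation parameter changes the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for model in bundle.registry:
        path = directory / f"{model.model_id}.hmm"
        write_hmmer3_profile(model, path)
        written.append(path)
    path = directory / "assignments.tsv"
    write_assignments_tsv(list(bundle.assignments), path)
    written.append(path)
    path = directory / "variants.tsv"
    write_variants_tsv(bundle.variants, path)
    written.append(path)
    path = directory / "membership.tsv"
    write_membership_tsv(bundle.memberships, path)
    written.append(path)
    path = directory / "truth.json"
    path.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True) + "\n")
    written.append(path)

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
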