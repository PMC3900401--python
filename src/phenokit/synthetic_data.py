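"""Ground-truth generators for every input the pipeline consumes.

Four synthetic input kinds, each with the planted truth attached so
downstream stages are testable without external data:

* a protein domain-family alignment evolved along a simulated balanced
  bifurcating tree, with planted invariant (catalytic-like) columns and
  optional class-specific columns constant within top-level clades;
* a CA-only toy structure with a planted spatial cluster of residues;
* an elastoplastic three-point-bending load-displacement curve (toe
  region, linear elastic rise, linear post-yield, drop to zero at
  failure) with Gaussian load noise and closed-form property truths;
* an averaged full-scan peak list for a tryptic peptide's PTM variants,
  including an isobaric 4-Hyp share phi of the +15.9949 Da ion, with
  multiplicative log-normal intensity noise;
* per-field fibril-diameter tables (by default 15 fields x 10 fibrils
  per animal, i.e. 150 measurements), log-normal diameters.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomechanics import LoadDisplacementCurve
from .constants import AMINO_ACIDS, OXYGEN_SHIFT_DA, PROTON_MASS_DA
from .evotrace import Alignment, PhyloTree, StructureModel, TreeNode, partition_at
from .ptm_occupancy import ScanTable


# ---------------------------------------------------------------------------
# Specs


@dataclass
class FamilySimSpec:
    """Design of a simulated domain-family alignment."""

    n_sequences: int
    n_columns: int
    invariant_positions: list[int] = field(default_factory=list)
    class_specific_positions: list[int] = field(default_factory=list)
    n_classes: int = 2
    substitution_rate: float = 0.05  # per-branch mutation probability per site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2 or self.n_columns < 1:
            raise ValueError("need at least 2 sequences and 1 column")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_classes > self.n_sequences:
            raise ValueError("n_classes cannot exceed n_sequences")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        inv, cls = set(self.invariant_positions), set(self.class_specific_positions)
        if inv & cls:
            raise ValueError("invariant and class-specific positions overlap")
        for pos in inv | cls:
            if not 1 <= pos <= self.n_columns:
                raise ValueError(f"position {pos} outside 1..{self.n_columns}")


@dataclass
class BeamSimSpec:
    """Bilinear elastoplastic beam with a zero-load toe region."""

    span_mm: float = 7.0
    diameter_mm: float = 1.5
    csmi_mm4: float = 0.2
    stiffness_N_per_mm: float = 120.0
    yield_load_N: float = 15.0
    postyield_slope_N_per_mm: float = 30.0
    failure_disp_mm: float = 0.6
    toe_disp_mm: float = 0.05
    noise_sd_N: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "span_mm",
            "diameter_mm",
            "csmi_mm4",
            "stiffness_N_per_mm",
            "yield_load_N",
            "postyield_slope_N_per_mm",
            "failure_disp_mm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.toe_disp_mm < 0 or self.noise_sd_N < 0:
            raise ValueError("toe displacement and noise sd must be non-negative")
        if self.postyield_slope_N_per_mm >= self.stiffness_N_per_mm:
            raise ValueError("post-yield slope must be below the elastic stiffness")
        if self.failure_disp_mm <= self.yield_disp_mm:
            raise ValueError("failure must occur beyond the yield displacement")

    @property
    def yield_disp_mm(self) -> float:
        return self.toe_disp_mm + self.yield_load_N / self.stiffness_N_per_mm


@dataclass
class ScanSimSpec:
    """Averaged full scan of one peptide's PTM variants."""

    base_mass_Da: float
    charge: int = 2
    variant_mass_shifts_Da: list[float] = field(default_factory=lambda: [0.0])
    variant_abundances: list[float] = field(default_factory=lambda: [1.0])
    isobaric_fraction: float = 0.0  # phi, applies to the +15.9949 Da variant
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_mass_Da <= 0:
            raise ValueError("base mass must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if len(self.variant_mass_shifts_Da) != len(self.variant_abundances):
            raise ValueError("shifts and abundances must have equal length")
        ab = np.asarray(self.variant_abundances, dtype=float)
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 (within 1e-9)")
        if not 0.0 <= self.isobaric_fraction <= 1.0:
            raise ValueError("isobaric fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


@dataclass
class FibrilSimSpec:
    """Per-field fibril diameter sampling design (fields x fibrils per animal)."""

    n_animals: int = 3
    fields_per_animal: int = 15
    fibrils_per_field: int = 10
    diameter_log_mean: float = np.log(100.0)  # log-nm
    diameter_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals, self.fields_per_animal, self.fibrils_per_field) < 1:
            raise ValueError("counts must be positive")
        if self.diameter_log_sd < 0:
            raise ValueError("log-sd must be non-negative")


# ---------------------------------------------------------------------------
# Family alignment


@dataclass
class TruthLabels:
    """Planted category of every alignment column."""

    invariant: list[int]
    class_specific: list[int]
    variable: list[int]

    def category(self, column: int) -> str:
        if column in self.invariant:
            return "invariant"
        if column in self.class_specific:
            return "class_specific"
        return "variable"


def _balanced_topology(ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Balanced bifurcating tree; node height = clade size + small Exp jitter.

    The jitter keeps heights distinct while guaranteeing that every
    parent is higher than its children, so cutting the n-1 highest nodes
    always yields the natural top-level clades.
    """
    if len(ids) == 1:
        return TreeNode(height=0.0, name=ids[0])
    half = (len(ids) + 1) // 2
    left = _balanced_topology(ids[:half], rng)
    right = _balanced_topology(ids[half:], rng)
    jitter = 0.01 * min(float(rng.exponential()), 50.0)
    return TreeNode(
        height=len(ids) + jitter,
        children=(left, right),
        leaves=left.leaves | right.leaves,
    )


def simulate_family_alignment(spec: FamilySimSpec):
    """Evolve an ungapped alignment along a simulated tree.

    Invariant positions are identical in every sequence; class-specific
    positions are constant within each of the ``n_classes`` top-level
    clades but differ between clades; all other columns mutate
    independently at ``substitution_rate`` per branch (uniform proposal
    over the other 19 letters).  When the rate is positive, a freely
    evolving column that happens to come out residue-constant across
    all leaves gets one leaf flipped so the planted truth stays
    recoverable by a direct column scan.

    Returns ``(Alignment, PhyloTree, TruthLabels)``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"seq{k:03d}" for k in range(1, spec.n_sequences + 1)]
    root = _balanced_topology(ids, rng)
    tree = PhyloTree(root)

    n_aa = len(AMINO_ACIDS)
    L = spec.n_columns
    root_seq = rng.integers(0, n_aa, size=L)
    leaf_seqs: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            leaf_seqs[node.name] = seq
            return
        for child in node.children:
            child_seq = seq.copy()
            if spec.substitution_rate > 0:
                mut = rng.random(L) < spec.substitution_rate
                n_mut = int(mut.sum())
                if n_mut:
                    child_seq[mut] = (
                        child_seq[mut] + rng.integers(1, n_aa, size=n_mut)
                    ) % n_aa
            evolve(child, child_seq)

    evolve(root, root_seq)
    codes = np.stack([leaf_seqs[sid] for sid in ids])

    invariant = sorted(spec.invariant_positions)
    class_specific = sorted(spec.class_specific_positions)
    planted = set(invariant) | set(class_specific)
    variable = [c for c in range(1, L + 1) if c not in planted]

    for col in invariant:
        codes[:, col - 1] = rng.integers(0, n_aa)

    if class_specific:
        clades = partition_at(tree, spec.n_classes).groups
        row_of = {sid: k for k, sid in enumerate(ids)}
        for col in class_specific:
            letters = rng.choice(n_aa, size=spec.n_classes, replace=False)
            for letter, clade in zip(letters, clades):
                for sid in clade:
                    codes[row_of[sid], col - 1] = letter

    if spec.substitution_rate > 0:
        for col in variable:
            column = codes[:, col - 1]
            if np.all(column == column[0]):
                row = int(rng.integers(0, spec.n_sequences))
                column[row] = (column[row] + int(rng.integers(1, n_aa))) % n_aa

    letters = np.array(list(AMINO_ACIDS))
    aln = Alignment(ids, letters[codes])
    truth = TruthLabels(
        invariant=invariant, class_specific=class_specific, variable=variable
    )
    return aln, tree, truth


# ---------------------------------------------------------------------------
# Toy structure


def simulate_toy_structure(
    n_residues: int,
    clustered_positions=(),
    cluster_radius_A: float = 8.0,
    seed: int = 0,
) -> StructureModel:
    """CA-only model with the listed residues planted inside one ball.

    Clustered residues are placed uniformly in a ball of radius
    ``cluster_radius_A`` (so every pairwise distance is at most twice
    the radius); the remaining residues follow a self-avoiding random
    walk with 3.8 A steps well away from the cluster.  Coordinates are
    rounded to 0.001 A so PDB round-trips are lossless.
    """
    if n_residues < 1:
        raise ValueError("need at least 1 residue")
    if cluster_radius_A <= 0:
        raise ValueError("cluster radius must be positive")
    clustered = sorted(set(int(p) for p in clustered_positions))
    for pos in clustered:
        if not 1 <= pos <= n_residues:
            raise ValueError(f"clustered position {pos} outside 1..{n_residues}")
    rng = np.random.default_rng(seed)
    coords: dict[int, np.ndarray] = {}

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    cluster_points = [
        random_unit() * cluster_radius_A * rng.random() ** (1.0 / 3.0)
        for _ in clustered
    ]
    placed: list[np.ndarray] = list(cluster_points)
    current = np.array([cluster_radius_A + 15.0, 0.0, 0.0])
    cluster_iter = iter(cluster_points)
    for res in range(1, n_residues + 1):
        if res in clustered:
            point = next(cluster_iter)
        else:
            point = current
            for _ in range(100):  # self-avoidance: retry clashing steps
                candidate = current + 3.8 * random_unit()
                if all(np.linalg.norm(candidate - q) >= 3.0 for q in placed):
                    point = candidate
                    break
            else:
                point = candidate
            current = point
            placed.append(point)
        coords[res] = np.round(point, 3)
    return StructureModel(coords)


# ---------------------------------------------------------------------------
# Load-displacement curve


@dataclass
class OffsetYieldTruth:
    """Closed-form result of the offset-yield construction on the ideal curve."""

    offset_mm: float
    yield_disp_mm: float
    yield_load_N: float
    elastic_energy_Nmm: float
    postyield_energy_Nmm: float

    @property
    def energy_to_failure_Nmm(self) -> float:
        return self.elastic_energy_Nmm + self.postyield_energy_Nmm


@dataclass
class BeamTruth:
    """Closed-form ground truth of the simulated bilinear beam.

    ``yield_*`` and the energies refer to the bilinear corner (triangle /
    trapezoid areas); :meth:`offset_truth` gives the values the offset
    yield construction ideally extracts from the noiseless curve, which
    sit slightly past the corner by design of the offset method.
    """

    stiffness_N_per_mm: float
    postyield_slope_N_per_mm: float
    toe_disp_mm: float
    yield_disp_mm: float
    yield_load_N: float
    max_load_N: float
    failure_disp_mm: float
    elastic_energy_Nmm: float
    postyield_energy_Nmm: float

    @property
    def energy_to_failure_Nmm(self) -> float:
        return self.elastic_energy_Nmm + self.postyield_energy_Nmm

    def offset_truth(self, offset_mm: float) -> OffsetYieldTruth:
        k = self.stiffness_N_per_mm
        k2 = self.postyield_slope_N_per_mm
        fy = self.yield_load_N
        xy = fy / k  # local coords past the toe
        x_star = xy + k * offset_mm / (k - k2)
        x_fail = self.failure_disp_mm - self.toe_disp_mm
        if x_star >= x_fail:
            raise ValueError("offset intersection lies beyond the failure point")
        f_star = fy + k * k2 * offset_mm / (k - k2)
        elastic = fy * xy / 2.0 + (fy + f_star) / 2.0 * (x_star - xy)
        post = (f_star + self.max_load_N) / 2.0 * (x_fail - x_star)
        return OffsetYieldTruth(
            offset_mm=offset_mm,
            yield_disp_mm=self.toe_disp_mm + x_star,
            yield_load_N=f_star,
            elastic_energy_Nmm=elastic,
            postyield_energy_Nmm=post,
        )


def simulate_load_displacement(spec: BeamSimSpec, n_samples: int = 2000):
    """Sample the piecewise beam response on a uniform displacement grid.

    Zero load over the toe, linear elastic rise to the yield load,
    linear post-yield rise to the failure displacement, then the load
    drops to zero; Gaussian noise of sd ``noise_sd_N`` is added to every
    load sample.  Returns ``(LoadDisplacementCurve, BeamTruth)``.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(spec.seed)
    k = spec.stiffness_N_per_mm
    k2 = spec.postyield_slope_N_per_mm
    toe = spec.toe_disp_mm
    xy = spec.yield_load_N / k
    d = np.linspace(0.0, spec.failure_disp_mm * 1.02, n_samples)
    x = d - toe
    load = np.where(
        x <= 0,
        0.0,
        np.where(
            x <= xy,
            k * x,
            spec.yield_load_N + k2 * (x - xy),
        ),
    )
    load[d >= spec.failure_disp_mm] = 0.0
    if spec.noise_sd_N > 0:
        load = load + rng.normal(0.0, spec.noise_sd_N, size=n_samples)
    curve = LoadDisplacementCurve(
        d, load, specimen_id=f"sim-beam-seed{spec.seed}"
    )
    x_fail = spec.failure_disp_mm - toe
    max_load = spec.yield_load_N + k2 * (x_fail - xy)
    truth = BeamTruth(
        stiffness_N_per_mm=k,
        postyield_slope_N_per_mm=k2,
        toe_disp_mm=toe,
        yield_disp_mm=toe + xy,
        yield_load_N=spec.yield_load_N,
        max_load_N=max_load,
        failure_disp_mm=spec.failure_disp_mm,
        elastic_energy_Nmm=spec.yield_load_N**2 / (2.0 * k),
        postyield_energy_Nmm=(spec.yield_load_N + max_load) / 2.0 * (x_fail - xy),
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Scan table


@dataclass
class OccupancyTruth:
    """Planted modification occupancy behind a simulated scan."""

    occupancy_percent: float  # summed abundance of all modified variants
    phi: float
    corrected_3hyp_percent: float | None  # None when no +15.9949 Da variant


def simulate_scan_table(spec: ScanSimSpec):
    """Peak list with one ion per variant and log-normal intensity noise.

    Peak m/z = (base + shift + z * 1.00728) / z; intensities are
    proportional to abundances (zero-abundance variants emit no peak).
    Variants whose m/z coincide are merged into one peak.  Returns
    ``(ScanTable, OccupancyTruth)``.
    """
    rng = np.random.default_rng(spec.seed)
    shifts = np.asarray(spec.variant_mass_shifts_Da, dtype=float)
    ab = np.asarray(spec.variant_abundances, dtype=float)
    mz = (spec.base_mass_Da + shifts + spec.charge * PROTON_MASS_DA) / spec.charge
    scale = 1.0e6
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=ab.size)
    else:
        noise = np.ones(ab.size)
    intensity = scale * ab * noise
    keep = ab > 0
    mz, intensity = mz[keep], intensity[keep]
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    merged_mz: list[float] = []
    merged_int: list[float] = []
    for m, i in zip(mz, intensity):
        if merged_mz and abs(m - merged_mz[-1]) < 1e-9:
            merged_int[-1] += i
        else:
            merged_mz.append(float(m))
            merged_int.append(float(i))
    scan = ScanTable(np.array(merged_mz), np.array(merged_int))

    modified = shifts != 0.0
    occ = 100.0 * float(ab[modified].sum())
    plus16 = np.abs(shifts - OXYGEN_SHIFT_DA) < 1e-6
    corrected = None
    if plus16.any():
        corrected = 100.0 * (1.0 - spec.isobaric_fraction) * float(ab[plus16].sum())
    truth = OccupancyTruth(
        occupancy_percent=occ,
        phi=spec.isobaric_fraction,
        corrected_3hyp_percent=corrected,
    )
    return scan, truth


# ---------------------------------------------------------------------------
# Fibril fields


def simulate_fibril_fields(
    spec: FibrilSimSpec, group_label: str = "sim"
) -> pd.DataFrame:
    """One row per measured fibril: (group, animal, field, diameter_nm).

    Diameters are log-normal; each animal contributes
    ``fields_per_animal * fibrils_per_field`` rows.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for animal in range(1, spec.n_animals + 1):
        for fld in range(1, spec.fields_per_animal + 1):
            diam = np.exp(
                rng.normal(
                    spec.diameter_log_mean,
                    spec.diameter_log_sd,
                    size=spec.fibrils_per_field,
                )
            )
            for d in diam:
                rows.append(
                    {
                        "group": group_label,
                        "animal": f"{group_label}-{animal}",
                        "field": fld,
                        "diameter_nm": float(d),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth sidecars


def write_truth(path, values: dict) -> None:
    """Flat key=value sidecar for planted ground truth."""
    with open(path, "w") as fh:
        for key, val in values.items():
            fh.write(f"{key}={val}\n")


def read_truth(path) -> dict:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, val = line.split("=", 1)
            out[key] = val
    return out
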