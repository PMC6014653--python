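"""Synthetic-data generators: two-layer craniometric populations and
damaged, contaminated ancient mtDNA read sets.

The craniometric generator draws population mean vectors as admixtures
``alpha * muB + (1 - alpha) * muA`` of two ancestral 16-dimensional layer
means (first layer A, second layer B) plus between-population drift and
within-population sampling noise — the statistical skeleton of a two-layer
settlement history.

The read generator fragments a genome into short, lognormally distributed
molecules, applies terminal cytosine deamination (C→T rising toward the 5'
end, G→A toward the 3' end at rate ``D * kappa^offset + epsilon``, the
double-strand library pattern), optionally mixes in longer undamaged
fragments from a contaminant genome, and emits paired reads with adapter
read-through and a fixed quality profile (Phred 37 with 1% of bases at 20,
so the Q30 pileup filter is exercised).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ValidationError
from .craniometrics import DEFAULT_PANEL_CODES, GroupMeanTable, MeasurementPanel
from .mito import Haplotree, MitoReference, VariantToken, apply_variants
from .readpipe import ADAPTER_R1, ADAPTER_R2, ReadRecord, revcomp

# plausible Martin-measurement magnitudes (mm) for the ancestral layers;
# only the generator's truth labels matter downstream, never these constants
_MU_A = np.array([182.0, 138.0, 94.0, 136.0, 106.0, 16.0, 130.0, 96.0,
                  24.0, 68.0, 41.0, 33.0, 26.0, 51.0, 8.5, 3.6])
_LAYER_CONTRAST = np.array([-4.0, 5.0, -2.5, 3.0, 3.0, -1.8, 4.0, 2.5,
                            -2.0, 3.0, 1.6, 2.0, -1.2, 2.0, -1.6, -1.0])


@dataclass
class TwoLayerModel:
    """Two ancestral layer means plus admixture/drift/noise parameters."""

    mu_a: np.ndarray = field(default_factory=lambda: _MU_A.copy())
    mu_b: np.ndarray = field(default_factory=lambda: (_MU_A + _LAYER_CONTRAST).copy())
    alphas: list[float] | None = None   # per-population admixture; None = half 0, half 1
    drift_sd: float = 1.0               # mm, between-population drift
    within_sd: float = 4.0              # mm, individual measurement SD
    seed: int = 0

    def __post_init__(self):
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_b = np.asarray(self.mu_b, dtype=float)
        if self.drift_sd <= 0 or self.within_sd <= 0:
            raise ValidationError("noise scales must be positive")
        if self.alphas is not None and any(not 0 <= a <= 1 for a in self.alphas):
            raise ValidationError("admixture coefficients must lie in [0, 1]")


def simulate_two_layer_table(model: TwoLayerModel, k_populations: int = 10,
                             n_per_population: int = 20,
                             panel: MeasurementPanel | None = None,
                             ) -> tuple[GroupMeanTable, dict[str, float]]:
    """Group-mean table plus the generating admixture coefficient per group."""
    if k_populations < 4:
        raise ValidationError("need k >= 4 populations")
    panel = panel or MeasurementPanel(DEFAULT_PANEL_CODES)
    rng = np.random.default_rng(model.seed)
    alphas = model.alphas
    if alphas is None:
        alphas = [0.0] * (k_populations // 2) + [1.0] * (k_populations - k_populations // 2)
    if len(alphas) != k_populations:
        raise ValidationError("len(alphas) != k_populations")
    p = len(panel.codes)
    groups, rows, truth = [], [], {}
    for g, a in enumerate(alphas):
        mean = a * model.mu_b + (1 - a) * model.mu_a
        mean = mean + rng.normal(0, model.drift_sd, p)
        mean = mean + rng.normal(0, model.within_sd / np.sqrt(n_per_population), p)
        label = f"pop{g:02d}_layer{'B' if a >= 0.5 else 'A'}"
        groups.append(label)
        rows.append(mean)
        truth[label] = float(a)
    table = GroupMeanTable(groups=groups, panel=panel, values=np.array(rows))
    return table, truth


# ---------------------------------------------------------------------------
# genomes and reads


@dataclass
class DamageParams:
    """Terminal deamination model: rate ``D * kappa^offset + epsilon``."""

    d: float = 0.3
    kappa: float = 0.5
    epsilon: float = 0.01
    library: str = "double"  # double-strand: symmetric 5' C→T / 3' G→A

    def __post_init__(self):
        if not (0 <= self.d <= 1 and 0 <= self.epsilon <= 1):
            raise ValidationError("rates must lie in [0, 1]")
        if self.d > 1e-6 and self.epsilon >= self.d:
            raise ValidationError("need epsilon < D (or D ~ 0 for no damage)")
        if not 0 < self.kappa < 1:
            raise ValidationError("need 0 < kappa < 1")

    def rate(self, offset) -> np.ndarray:
        return self.d * self.kappa ** np.asarray(offset, dtype=float) + self.epsilon


@dataclass
class FragmentModel:
    """Lognormal fragment lengths (median ~60 bp by default) and target depth."""

    median: float = 60.0
    sigma: float = 0.35
    min_length: int = 35
    mean_depth: float = 20.0

    def __post_init__(self):
        if self.min_length < 1 or self.mean_depth <= 0:
            raise ValidationError("min_length >= 1 and mean_depth > 0 required")

    def draw_lengths(self, n: int, rng, max_length: int) -> np.ndarray:
        lens = rng.lognormal(np.log(self.median), self.sigma, n)
        return np.clip(np.round(lens), self.min_length, max_length).astype(int)


def simulate_genome(tree: Haplotree, node: str, n_private: int, seed: int,
                    ref: MitoReference) -> tuple[str, list[VariantToken]]:
    """Genome carrying the root→node defining variants plus ``n_private``
    random SNPs at non-diagnostic positions; returns (sequence, truth)."""
    if node not in tree.nodes:
        raise ValidationError(f"unknown haplotree node {node!r}")
    rng = np.random.default_rng(seed)
    path = list(tree.path_variants(node))
    occupied = set()
    for t in path:
        occupied.update(range(t.pos, t.pos + len(t.ref) + 1))
    # reserve every tree-diagnostic position so private SNPs never collide
    for n_ in tree.nodes.values():
        for t in n_.variants:
            occupied.update(range(t.pos, t.pos + len(t.ref) + 1))
    privates: list[VariantToken] = []
    alphabet = "ACGT"
    while len(privates) < n_private:
        pos = int(rng.integers(1, len(ref) + 1))
        if pos in occupied:
            continue
        occupied.add(pos)
        r = ref.base(pos)
        alt = alphabet[int(rng.integers(0, 4))]
        while alt == r:
            alt = alphabet[int(rng.integers(0, 4))]
        privates.append(VariantToken(ref=r, pos=pos, alt=alt))
    variants = sorted(path + privates, key=lambda t: t.pos)
    return apply_variants(ref, variants), variants


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}
_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _fragments_matrix(genome: str, starts, lengths, rng):
    """Stack circular fragments (strand-randomised) into a padded byte matrix."""
    L = len(genome)
    ext = (genome + genome).encode()
    arr = np.frombuffer(ext, dtype=np.uint8)
    n = len(starts)
    maxlen = int(lengths.max())
    mat = np.zeros((n, maxlen), dtype=np.uint8)
    strands = rng.integers(0, 2, n)  # 1 = reverse
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    for i, (s, ln) in enumerate(zip(starts, lengths)):
        frag = arr[s:s + ln]
        if strands[i]:
            frag = comp[frag][::-1]
        mat[i, :ln] = frag
    return mat, strands


def _apply_damage(mat, lengths, damage: DamageParams, endo_mask, rng):
    """Vectorised 5' C→T / 3' G→A deamination on a padded fragment matrix."""
    n, maxlen = mat.shape
    col = np.arange(maxlen)[None, :]
    valid = col < lengths[:, None]
    off5 = col.astype(float)
    off3 = (lengths[:, None] - 1 - col).astype(float)
    d_eff = np.where(endo_mask[:, None], damage.d, 0.0)
    p_ct = d_eff * damage.kappa ** off5 + damage.epsilon
    p_ga = d_eff * damage.kappa ** off3 + damage.epsilon
    u = rng.random(mat.shape)
    is_c = mat == ord("C")
    is_g = mat == ord("G")
    mat[valid & is_c & (u < p_ct)] = ord("T")
    mat[valid & is_g & (u < p_ga)] = ord("A")
    return mat


def simulate_reads(genome: str, fragment_model: FragmentModel,
                   damage: DamageParams, *,
                   contaminant: tuple[str, float] | None = None,
                   contaminant_model: FragmentModel | None = None,
                   read_length: int = 100, seed: int = 0,
                   n_fragments: int | None = None,
                   ) -> tuple[list[tuple[ReadRecord, ReadRecord]], dict]:
    """Paired reads from damaged fragments of ``genome``.

    Fragment starts are uniform on the circle; lengths are lognormal,
    truncated so every pair overlaps enough to collapse. Contaminant
    fragments (undamaged apart from the background error, drawn from the
    contaminant genome with a longer length model) replace an expected
    ``fraction`` of molecules. Returns the pairs plus a truth manifest.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    max_len = 2 * read_length - 12  # collapsible by construction
    if n_fragments is None:
        exp_len = min(fragment_model.median * np.exp(fragment_model.sigma ** 2 / 2), max_len)
        n_fragments = max(1, int(round(fragment_model.mean_depth * L / exp_len)))

    frac = contaminant[1] if contaminant is not None else 0.0
    if not 0 <= frac < 1:
        raise ValidationError("contaminant fraction must lie in [0, 1)")
    endo_mask = rng.random(n_fragments) >= frac
    n_endo = int(endo_mask.sum())

    cmodel = contaminant_model or FragmentModel(median=120.0, sigma=0.30,
                                                min_length=fragment_model.min_length,
                                                mean_depth=fragment_model.mean_depth)
    lengths = np.where(endo_mask,
                       fragment_model.draw_lengths(n_fragments, rng, max_len),
                       cmodel.draw_lengths(n_fragments, rng, max_len))
    starts = rng.integers(0, L, n_fragments)

    mat, strands = _fragments_matrix(genome, starts, lengths, rng)
    if contaminant is not None and (~endo_mask).any():
        cgenome = contaminant[0]
        cmat, cstr = _fragments_matrix(cgenome, starts % len(cgenome), lengths, rng)
        mat[~endo_mask] = cmat[~endo_mask]
        strands = np.where(endo_mask, strands, cstr)
    mat = _apply_damage(mat, lengths, damage, endo_mask, rng)

    pairs = _emit_pairs(mat, lengths, read_length, rng)
    truth = {"n_fragments": n_fragments, "n_endogenous": n_endo,
             "n_contaminant": n_fragments - n_endo, "starts": starts,
             "lengths": lengths, "endogenous": endo_mask, "strands": strands}
    return pairs, truth


def _emit_pairs(mat, lengths, read_length, rng) -> list[tuple[ReadRecord, ReadRecord]]:
    n = mat.shape[0]
    a1 = np.frombuffer((ADAPTER_R1 + "A" * 400).encode(), dtype=np.uint8)
    a2 = np.frombuffer((ADAPTER_R2 + "A" * 400).encode(), dtype=np.uint8)
    # quality profile: Phred 37 with 1% of bases at 20; sequencing errors drawn
    # per base at the quality-implied rate
    q1 = np.where(rng.random((n, read_length)) < 0.01, 20, 37).astype(np.uint8)
    q2 = np.where(rng.random((n, read_length)) < 0.01, 20, 37).astype(np.uint8)
    pairs = []
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    err1 = rng.random((n, read_length))
    err2 = rng.random((n, read_length))
    shift = rng.integers(1, 4, (2, n, read_length))
    for i in range(n):
        ln = int(lengths[i])
        frag = mat[i, :ln]
        r1 = np.concatenate([frag, a1])[:read_length]
        r2 = np.concatenate([comp[frag][::-1], a2])[:read_length]
        for ridx, (r, e, q) in enumerate(((r1, err1[i], q1[i]), (r2, err2[i], q2[i]))):
            bad = e < 10.0 ** (-q.astype(np.float64) / 10.0)
            if bad.any():
                idx = np.flatnonzero(bad)
                code = np.array([_CODE.get(int(b), 0) for b in r[idx]])
                r[idx] = _LETTERS[(code + shift[ridx, i, idx]) % 4]
        pairs.append((
            ReadRecord(name=f"frag{i}", sequence=r1.tobytes().decode(), quality=q1[i]),
            ReadRecord(name=f"frag{i}", sequence=r2.tobytes().decode(), quality=q2[i]),
        ))
    return pairs


def make_cohort_fixture(seed: int = 0, tree: Haplotree | None = None,
                        ref: MitoReference | None = None) -> dict:
    """Deterministic desk-scale study bundle.

    A 30-group craniometric table (2 "early" first-layer groups, 20 "late"
    second-layer groups, 8 comparative groups split between the layers) and
    five individual read sets with depths spanning determinable (>= 20x)
    through undeterminable (< 3x) outcomes, plus a ground-truth manifest.
    """
    from .mito import demo_haplotree, demo_reference

    tree = tree or demo_haplotree()
    ref = ref or demo_reference()
    alphas = [0.0, 0.0] + [1.0] * 20 + [0.0] * 4 + [1.0] * 4
    model = TwoLayerModel(alphas=alphas, seed=seed)
    table, alpha_truth = simulate_two_layer_table(model, k_populations=len(alphas))
    labels = (["early_GH1", "early_GH2"] + [f"late_GH{i:02d}" for i in range(1, 21)]
              + [f"cmp_layerA{i}" for i in range(1, 5)]
              + [f"cmp_layerB{i}" for i in range(1, 5)])
    truth_alpha = dict(zip(labels, [alpha_truth[g] for g in table.groups]))
    table.groups = labels

    nodes = ["E1a1a1a", "B4a1a", "M", "F1a1a1", "Y2a1"]
    depths = [30.0, 25.0, 20.0, 1.5, 0.8]
    individuals = {}
    for j, (node, depth) in enumerate(zip(nodes, depths)):
        gseed = seed * 1000 + j
        genome, variants = simulate_genome(tree, node, n_private=3, seed=gseed, ref=ref)
        fm = FragmentModel(mean_depth=depth)
        pairs, truth = simulate_reads(genome, fm, DamageParams(), seed=gseed + 500)
        individuals[f"ind{j + 1}"] = {
            "node": node, "target_depth": depth, "pairs": pairs,
            "genome": genome, "variants": variants, "truth": truth,
        }
    return {"craniometric_table": table, "alpha_truth": truth_alpha,
            "individuals": individuals, "seed": seed}
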