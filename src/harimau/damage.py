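"""Ancient-DNA authenticity diagnostics.

Post-mortem cytosine deamination leaves excess C→T mismatches at read 5'
termini (and, in double-strand libraries, mirrored G→A at 3' termini) that
decay roughly geometrically with distance from the fragment end:
``d(i) = D * kappa^i + epsilon``. This module measures those profiles,
scores individual reads by a damage log-likelihood ratio (a PMD-style
score), estimates the modern-contamination fraction from the deficit of
terminal deamination, and implements the variant-read-length check used to
flag a lineage whose supporting fragments are suspiciously long and
undamaged (the signature of a modern contaminant haplotype).

All computations work on :class:`~harimau.readpipe.AlignedRead` objects in
read orientation, so both strands contribute to the same terminal profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from . import InsufficientDataError
from .mito import MitoReference, VariantToken
from .readpipe import AlignedRead
from .simulate import DamageParams


@dataclass
class MisincorporationProfile:
    """Terminal substitution frequencies by offset from each read end."""

    ct5: np.ndarray       # C→T frequency at 5' offsets 0..W-1
    ga3: np.ndarray       # G→A frequency at 3' offsets 0..W-1
    ct5_counts: np.ndarray  # reference-C contexts per offset
    ga3_counts: np.ndarray
    window: int = 25

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tct5_freq\tct5_n\tga3_freq\tga3_n\n")
            for i in range(self.window):
                fh.write(f"{i}\t{self.ct5[i]:.6f}\t{self.ct5_counts[i]}\t"
                         f"{self.ga3[i]:.6f}\t{self.ga3_counts[i]}\n")


def _terminal_arrays(read: AlignedRead, window: int,
                     exclude: set[int] | None = None, ref_length: int = 0):
    """(ctx5, hit5, ctx3, hit3) boolean arrays over offsets 0..window-1.

    Positions whose (wrapped) reference coordinate is in ``exclude`` — e.g.
    the sample's own consensus variants, which would otherwise masquerade as
    damage — contribute no context.
    """
    n = len(read)
    w = min(window, n)
    rb = read.refbase
    sq = read.sequence
    ctx5 = np.zeros(window, bool)
    hit5 = np.zeros(window, bool)
    ctx3 = np.zeros(window, bool)
    hit3 = np.zeros(window, bool)

    def excluded(idx: int) -> bool:
        if not exclude:
            return False
        p = int(read.refpos[idx])
        if p <= 0:
            return True
        if ref_length:
            p = (p - 1) % ref_length + 1
        return p in exclude

    use5 = getattr(read, "trim5", 0) == 0
    use3 = getattr(read, "trim3", 0) == 0
    for i in range(w):
        if use5 and rb[i] == "C" and not excluded(i):
            ctx5[i] = True
            hit5[i] = sq[i] == "T"
        j = n - 1 - i
        if use3 and rb[j] == "G" and not excluded(j):
            ctx3[i] = True
            hit3[i] = sq[j] == "A"
    return ctx5, hit5, ctx3, hit3


def misincorporation_profile(aligned: list[AlignedRead], ref: MitoReference | None = None,
                             window: int = 25,
                             exclude: set[int] | None = None) -> MisincorporationProfile:
    """Observed C→T (5') and G→A (3') frequencies by terminal offset.

    ``exclude`` lists reference positions (e.g. the sample's consensus
    variants) to drop from the contexts.
    """
    c5 = np.zeros(window)
    h5 = np.zeros(window)
    c3 = np.zeros(window)
    h3 = np.zeros(window)
    L = len(ref) if ref is not None else 0
    for r in aligned:
        ctx5, hit5, ctx3, hit3 = _terminal_arrays(r, window, exclude, L)
        c5 += ctx5
        h5 += hit5
        c3 += ctx3
        h3 += hit3
    with np.errstate(invalid="ignore"):
        f5 = np.where(c5 > 0, h5 / np.maximum(c5, 1), 0.0)
        f3 = np.where(c3 > 0, h3 / np.maximum(c3, 1), 0.0)
    return MisincorporationProfile(ct5=f5, ga3=f3,
                                   ct5_counts=c5.astype(int),
                                   ga3_counts=c3.astype(int), window=window)


@dataclass
class LengthDistribution:
    """Histogram and summaries of merged mapped read lengths."""

    histogram: np.ndarray   # counts indexed by length
    mean: float
    median: float
    short_fragment_verdict: bool

    @classmethod
    def empty(cls):
        return cls(histogram=np.zeros(1, dtype=int), mean=0.0, median=0.0,
                   short_fragment_verdict=False)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for ln, c in enumerate(self.histogram):
                if c:
                    fh.write(f"{ln}\t{c}\n")


def fragment_length_stats(aligned: list[AlignedRead], *,
                          short_threshold: float = 100.0) -> LengthDistribution:
    if not aligned:
        return LengthDistribution.empty()
    lengths = np.array([len(r) for r in aligned])
    hist = np.bincount(lengths)
    med = float(np.median(lengths))
    return LengthDistribution(histogram=hist, mean=float(lengths.mean()),
                              median=med,
                              short_fragment_verdict=med < short_threshold)


def pmd_score(read: AlignedRead, ref: MitoReference | None = None,
              damage_model: DamageParams | None = None) -> float:
    """Log-likelihood ratio of the damage model vs error-only for one read.

    Sums, over reference-C positions near the 5' end and reference-G
    positions near the 3' end, ``log P(obs | d(i)) - log P(obs | epsilon)``
    with ``d(i) = D * kappa^i + epsilon``. Positive scores indicate a
    damage-consistent read; reads without C/G context score 0.
    """
    dm = damage_model or DamageParams()
    n = len(read)
    score = 0.0
    for i in range(n):
        r5 = read.refbase[i]
        if r5 == "C":
            d = dm.d * dm.kappa ** i + dm.epsilon
            obs_t = read.sequence[i] == "T"
            p1 = d if obs_t else 1.0 - d
            p0 = dm.epsilon if obs_t else 1.0 - dm.epsilon
            score += math.log(p1 / p0)
        if r5 == "G":
            j = n - 1 - i  # offset from the 3' end
            d = dm.d * dm.kappa ** j + dm.epsilon
            obs_a = read.sequence[i] == "A"
            p1 = d if obs_a else 1.0 - d
            p0 = dm.epsilon if obs_a else 1.0 - dm.epsilon
            score += math.log(p1 / p0)
    return score


# ---------------------------------------------------------------------------
# contamination


def _fmt_half_pct(x: float) -> str:
    v = round(x * 200.0) / 2.0
    return f"{v:g}"


@dataclass
class ContaminationEstimate:
    point: float
    lo: float
    hi: float
    n_reads: int
    damage_rate: float      # estimated endogenous terminal rate D̂
    status: str = "ok"

    def __str__(self):
        return (f"{_fmt_half_pct(self.point)}% "
                f"[{_fmt_half_pct(self.lo)}–{_fmt_half_pct(self.hi)}%]")


_N_OFF = 11   # offsets 0..10 enter the decay fit
_N_WIN = 25   # offsets tracked per read; 12..24 estimate the background
_COND_W = 3   # opposite-terminus window defining the conditioned subset


_COL_COND5 = 4 * _N_WIN
_COL_COND3 = 4 * _N_WIN + 1
_COL_LEN = 4 * _N_WIN + 2


def _read_features(aligned: list[AlignedRead], length_min: int,
                   exclude: set[int] | None = None,
                   ref_length: int = 0) -> np.ndarray:
    """Per-read terminal context/hit indicators plus the read length.

    Columns: [ctx5(25), hit5(25), ctx3(25), hit3(25), cond5, cond3, length]
    where cond5 marks reads with a damage-consistent G→A within the first
    three 3' offsets (conditioning the 5' profile on endogenous molecules)
    and cond3 the mirror image.
    """
    rows = []
    for r in aligned:
        if len(r) < length_min:
            continue
        ctx5, hit5, ctx3, hit3 = _terminal_arrays(r, _N_WIN, exclude, ref_length)
        cond5 = bool(hit3[:_COND_W].any())
        cond3 = bool(hit5[:_COND_W].any())
        rows.append(np.concatenate([ctx5, hit5, ctx3, hit3,
                                    [cond5, cond3, len(r)]]))
    if not rows:
        return np.zeros((0, _COL_LEN + 1))
    return np.array(rows, dtype=np.float32)


def _background_rate(feat: np.ndarray, w: np.ndarray) -> float | None:
    """Background mismatch rate from deep interior offsets (12..24), where
    decayed damage is negligible relative to sequencing/alignment error."""
    W = _N_WIN
    sums = w @ feat
    all_ctx = sums[0:W] + sums[2 * W:3 * W]
    all_hit = sums[W:2 * W] + sums[3 * W:4 * W]
    deep = slice(12, W)
    if all_ctx[deep].sum() < 100:
        return None
    return float(max(all_hit[deep].sum() / all_ctx[deep].sum(), 1e-5))


def _estimate_from_features(feat: np.ndarray, w: np.ndarray | None = None,
                            x0=None):
    """Point estimate (c_hat, D_hat, eps_hat, kappa_hat) by maximum likelihood.

    Terminal hits over offsets 0..24 of both termini are modelled as a
    two-component mixture: an endogenous read damages each C (5') / G (3')
    context at offset ``i`` with probability ``D * kappa^i + eps_e``; a
    contaminant read at a flat rate ``eps_c``. Separate background floors
    matter because private variants of either genome masquerade as a small
    flat mismatch rate specific to their component. The per-read joint hit
    pattern identifies the mixture weight ``c``. Returns None on degenerate
    input.
    """
    from scipy.optimize import minimize

    if w is None:
        w = np.ones(feat.shape[0], dtype=np.float32)
    eps0 = _background_rate(feat, w)
    if eps0 is None:
        return None
    W = _N_WIN
    ctx = np.concatenate([feat[:, 0:W], feat[:, 2 * W:3 * W]], axis=1)
    hit = np.concatenate([feat[:, W:2 * W], feat[:, 3 * W:4 * W]], axis=1)
    miss = ctx - hit
    offs = np.concatenate([np.arange(W), np.arange(W)]).astype(float)
    hit_tot = hit.sum(axis=1)
    miss_tot = miss.sum(axis=1)

    def negloglik(theta):
        c, d, kap, eps_e, eps_c = theta
        rate = np.clip(d * kap ** offs + eps_e, 1e-9, 1 - 1e-9)
        ll_endo = hit @ np.log(rate) + miss @ np.log1p(-rate)
        ll_cont = hit_tot * np.log(eps_c) + miss_tot * np.log1p(-eps_c)
        mix = np.logaddexp(np.log1p(-c) + ll_endo, np.log(max(c, 1e-12)) + ll_cont)
        return -float(w @ mix)

    if x0 is None:
        x0 = (0.1, 0.25, 0.5, eps0, eps0)
    # the contaminant floor exceeds the endogenous background only through
    # the contaminant genome's private variants, a small increment; leaving
    # it fully free lets a spurious "noisy flat" component form in small
    # samples
    res = minimize(negloglik, x0=np.array(x0), method="L-BFGS-B",
                   bounds=[(1e-6, 0.999), (1e-4, 1.0), (0.05, 0.95),
                           (1e-5, 0.2), (1e-5, min(eps0 + 0.005, 0.2))])
    if not res.success and res.status != 1:  # status 1 = maxiter, still usable
        return None
    c_hat, d_hat, kap_hat, eps_e, eps_c = res.x
    if c_hat < 2e-6:
        c_hat = 0.0
    return float(c_hat), float(d_hat), float(eps_e), float(kap_hat), float(eps_c)


def _em_estimate(feat: np.ndarray, init):
    """Refine the damage-only mixture with a fragment-length channel.

    Undamaged modern contaminants are typically longer than endogenous
    ancient fragments, so fragment length carries real mixture information.
    To keep the model identifiable the channels are treated asymmetrically:
    the endogenous length density is a fixed nonparametric plug-in estimated
    from reads with terminal damage at offsets 0-2 (an almost purely
    endogenous subset, and within a class damage is independent of length),
    corrected for the small contaminant leakage into that subset; the
    contaminant length component is a parametric lognormal fit jointly with
    the mixture weight over the combined damage x length likelihood. With
    negligible contaminant mass, or indistinguishable length distributions,
    the refit reduces to the damage-only estimate.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.optimize import minimize

    c0, d0, ee0, kap0, ec0 = init
    W = _N_WIN
    ctx = np.concatenate([feat[:, 0:W], feat[:, 2 * W:3 * W]], axis=1)
    hit = np.concatenate([feat[:, W:2 * W], feat[:, 3 * W:4 * W]], axis=1)
    miss = ctx - hit
    offs = np.concatenate([np.arange(W), np.arange(W)]).astype(float)
    hit_tot, miss_tot = hit.sum(1), miss.sum(1)
    loglen = np.log(feat[:, _COL_LEN].astype(np.float64))

    rate = np.clip(d0 * kap0 ** offs + ee0, 1e-9, 1 - 1e-9)
    ec = min(max(ec0, 1e-5), 0.5)
    lle0 = hit @ np.log(rate) + miss @ np.log1p(-rate)
    llc0 = hit_tot * np.log(ec) + miss_tot * np.log1p(-ec)

    sel = np.concatenate([np.arange(3), W + np.arange(3)])
    damaged = hit[:, sel].sum(1) >= 1
    if damaged.sum() < 200:
        return (float(c0 if c0 > 2e-6 else 0.0), d0, ee0, kap0, ec0,
                lle0, llc0)

    edges = np.linspace(loglen.min() - 1e-6, loglen.max() + 1e-6, 61)
    width = edges[1] - edges[0]
    centers = (edges[:-1] + edges[1:]) / 2.0
    bin_of = np.clip(np.digitize(loglen, edges) - 1, 0, 59)

    def hist_density(weights):
        h, _ = np.histogram(loglen, bins=edges,
                            weights=np.asarray(weights, dtype=np.float64))
        h = gaussian_filter1d(h, sigma=1.5, mode="nearest")
        return np.clip(h / max(h.sum() * width, 1e-300), 1e-9, None)

    def normal_ld(x, mu, sg):
        return -np.log(sg) - 0.5 * np.log(2 * np.pi) \
            - (x - mu) ** 2 / (2 * sg * sg)

    # per-class probabilities of entering the damage-selected subset
    q_e = 1.0 - float(np.exp(
        (np.log1p(-rate)[sel][None, :] * ctx[:, sel]).sum(1)).mean())
    q_c = 1.0 - float(np.exp(
        np.log1p(-ec) * (hit[:, sel] + miss[:, sel]).sum(1)).mean())

    f_sel = hist_density(damaged.astype(np.float64))
    mu_all, sg_all = float(loglen.mean()), float(max(loglen.std(), 0.05))
    qtl = np.quantile(loglen, 0.9)
    tail = loglen[loglen >= qtl]
    bounds = [(1e-6, 0.999), (float(loglen.min()), float(loglen.max())),
              (0.03, 2.0)]

    c, mu_c, sg_c = max(c0, 0.01), float(tail.mean()), float(max(tail.std(), 0.05))
    for _ in range(3):
        # endogenous density corrected for contaminant leakage into the
        # damage-selected subset
        lam = c * q_c / max((1 - c) * q_e + c * q_c, 1e-12)
        f_cont_bins = np.exp(normal_ld(centers, mu_c, sg_c))
        f_endo = np.clip((f_sel - lam * f_cont_bins) / max(1 - lam, 1e-6),
                         1e-9, None)
        f_endo /= f_endo.sum() * width
        lle = lle0 + np.log(f_endo)[bin_of]

        def negloglik(theta):
            cv, mu, sg = theta
            llc = llc0 + normal_ld(loglen, mu, sg)
            return -float(np.logaddexp(np.log1p(-cv) + lle,
                                       np.log(max(cv, 1e-12)) + llc).sum())

        best = None
        for x0 in ((c, mu_c, sg_c), (c, mu_all, sg_all)):
            res = minimize(negloglik, x0=np.array(x0), method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        c_new, mu_c, sg_c = (float(best.x[0]), float(best.x[1]),
                             float(best.x[2]))
        if abs(c_new - c) < 1e-4:
            c = c_new
            break
        c = c_new

    llc = llc0 + normal_ld(loglen, mu_c, sg_c)
    return (float(c if c > 2e-6 else 0.0), float(d0), float(ee0),
            float(kap0), float(ec0), lle, llc)


def _component_logliks(feat: np.ndarray, d: float, kap: float, eps_e: float,
                       eps_c: float):
    W = _N_WIN
    ctx = np.concatenate([feat[:, 0:W], feat[:, 2 * W:3 * W]], axis=1)
    hit = np.concatenate([feat[:, W:2 * W], feat[:, 3 * W:4 * W]], axis=1)
    miss = ctx - hit
    offs = np.concatenate([np.arange(W), np.arange(W)]).astype(float)
    rate = np.clip(d * kap ** offs + eps_e, 1e-9, 1 - 1e-9)
    lle = hit @ np.log(rate) + miss @ np.log1p(-rate)
    ec = min(max(eps_c, 1e-5), 0.5)
    llc = hit.sum(1) * np.log(ec) + miss.sum(1) * np.log1p(-ec)
    return lle, llc


def _fit_weight_only(lle, llc, w, c0: float) -> float:
    from scipy.optimize import minimize_scalar

    def nll(c):
        return -float(w @ np.logaddexp(np.log1p(-c) + lle, np.log(c) + llc))

    res = minimize_scalar(nll, bounds=(1e-6, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x) if res.x > 2e-6 else 0.0


def estimate_contamination(aligned: list[AlignedRead], ref: MitoReference | None = None,
                           *, length_min: int = 40, n_boot: int = 500,
                           seed: int = 0,
                           exclude: set[int] | None = None) -> ContaminationEstimate:
    """Deamination-based modern-contamination estimate with bootstrap CI.

    Endogenous molecules damage terminal C (5') / G (3') contexts at the
    decaying rate ``D * kappa^i + eps`` while contaminant molecules show only
    the background ``eps`` (measured at deep interior offsets); the per-read
    pattern of terminal hits over offsets 0..10 of both ends is fit as a
    two-component mixture by maximum likelihood, whose weight is the
    contamination fraction. Only reads of length >= ``length_min``
    contribute (deamination conditioning contract; double-strand library
    symmetry assumed). The 95% interval is a nonparametric bootstrap over
    reads, and the formatted string rounds to 0.5% steps.
    """
    feat = _read_features(aligned, length_min, exclude,
                          len(ref) if ref is not None else 0)
    n = feat.shape[0]
    term_ctx = int(feat[:, 0].sum() + feat[:, 2 * _N_OFF].sum())
    if term_ctx < 200:
        raise InsufficientDataError(
            f"only {term_ctx} terminal C/G contexts (< 200): cannot estimate "
            f"contamination")
    est = _estimate_from_features(feat)
    if est is None:
        raise InsufficientDataError("degenerate deamination mixture fit")
    c0, d0, eps0, kap0, epsc0 = est
    c_hat, d_hat, eps_hat, kap_hat, eps_c, lle, llc = _em_estimate(
        feat, (c0, d0, eps0, kap0, epsc0))
    rng = np.random.default_rng(seed)
    # bootstrap resamples reads and refits the mixture weight with the
    # damage and length components held at their point estimates
    boots = []
    for _ in range(n_boot):
        w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(np.float64)
        boots.append(_fit_weight_only(lle, llc, w, c_hat))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c_hat
    lo = min(float(lo), c_hat)
    hi = max(float(hi), c_hat)
    return ContaminationEstimate(point=c_hat, lo=lo, hi=hi, n_reads=n,
                                 damage_rate=d_hat)


# ---------------------------------------------------------------------------
# variant-supporting read length check


@dataclass
class VariantLengthReport:
    variant: str
    n_variant: int
    n_damaged: int
    n_other: int
    mean_len_variant: float
    mean_len_damaged: float
    mean_len_other: float
    p_value: float
    flagged: bool
    status: str = "ok"


def variant_read_length_flag(aligned: list[AlignedRead], ref: MitoReference,
                             variant: VariantToken, *, margin: float = 0.20,
                             alpha: float = 0.05,
                             terminal_window: int = 3) -> VariantLengthReport:
    """Flag a variant whose carrier reads are suspiciously long.

    Reads covering the variant position are partitioned into (a) carriers of
    the alternate allele, (b) damage-authentic reads (a C→T or G→A within
    ``terminal_window`` bases of either end), and (c) the rest. The flag
    fires when the carriers' mean length exceeds the damaged reads' mean by
    more than ``margin`` with a one-sided rank-sum p below ``alpha`` — the
    pattern of a modern contaminant lineage.
    """
    L = len(ref)
    pos = variant.pos
    carriers, damaged, other = [], [], []
    for r in aligned:
        wrapped = (r.refpos - 1) % L + 1
        hitpos = np.flatnonzero((wrapped == pos) & (r.refpos > 0))
        if hitpos.size == 0:
            continue
        i = int(hitpos[0])
        base = r.sequence[i] if r.strand == "+" else r.sequence[i].translate(
            str.maketrans("ACGT", "TGCA"))
        ctx5, hit5, ctx3, hit3 = _terminal_arrays(r, terminal_window)
        is_damaged = bool(hit5.any() or hit3.any())
        if base == variant.alt[-1] and base != variant.ref[0]:
            carriers.append(len(r))
        elif is_damaged:
            damaged.append(len(r))
        else:
            other.append(len(r))
    if len(carriers) + len(damaged) + len(other) < 5 or not carriers:
        return VariantLengthReport(variant=str(variant), n_variant=len(carriers),
                                   n_damaged=len(damaged), n_other=len(other),
                                   mean_len_variant=float(np.mean(carriers)) if carriers else 0.0,
                                   mean_len_damaged=float(np.mean(damaged)) if damaged else 0.0,
                                   mean_len_other=float(np.mean(other)) if other else 0.0,
                                   p_value=1.0, flagged=False, status="insufficient coverage")
    mv = float(np.mean(carriers))
    md = float(np.mean(damaged)) if damaged else 0.0
    if damaged and len(carriers) >= 2:
        p = float(mannwhitneyu(carriers, damaged, alternative="greater").pvalue)
    else:
        p = 1.0
    flagged = bool(damaged) and mv > (1.0 + margin) * md and p < alpha
    return VariantLengthReport(variant=str(variant), n_variant=len(carriers),
                               n_damaged=len(damaged), n_other=len(other),
                               mean_len_variant=mv, mean_len_damaged=md,
                               mean_len_other=float(np.mean(other)) if other else 0.0,
                               p_value=p, flagged=flagged)
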