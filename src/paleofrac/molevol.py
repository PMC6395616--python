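"""Molecular-evolution estimates: Ka/Ks (NG86) and Ks-distribution dating.

Ka and Ks are computed with the Nei-Gojobori (1986) counting method under the
universal genetic code: per-codon synonymous/nonsynonymous site fractions are
averaged over both sequences, observed differences are classified by averaging
over all minimal mutational pathways between the two codons (pathways passing
through a stop codon are excluded when an alternative exists), and the
Jukes-Cantor correction d = -3/4 ln(1 - 4p/3) is applied to both proportions.

Block ages are summarised as the median pair Ks, and the genome-wide block-Ks
distribution is decomposed with a one-dimensional Gaussian mixture fitted by
EM, which separates the speciation peak from the older shared-WGD peak so
blocks descending from the ancient event can be stripped before subgenome
reconstruction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: amino acid per codon index; '*' marks stops
AMINO = np.array(
    [("*" if c in _TABLE.stop_codons else _TABLE.forward_table[c]) for c in CODONS]
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def _build_site_fractions() -> np.ndarray:
    """Synonymous site count per codon (mutations to stops = nonsynonymous)."""
    syn = np.zeros(64)
    for i, codon in enumerate(CODONS):
        if AMINO[i] == "*":
            syn[i] = np.nan
            continue
        s = 0.0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                j = _CODON_INDEX[mut]
                if AMINO[j] == AMINO[i]:
                    s += 1 / 3
        syn[i] = s
    return syn


def _build_pathway_tables() -> tuple[np.ndarray, np.ndarray]:
    """Expected synonymous/nonsynonymous differences per codon pair.

    Averages step classifications over all orderings of the differing
    positions; pathways via stop codons are dropped unless every pathway is
    blocked, in which case all pathways are used.
    """
    syn_d = np.zeros((64, 64))
    nonsyn_d = np.zeros((64, 64))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j or AMINO[i] == "*" or AMINO[j] == "*":
                continue
            diff_pos = [p for p in range(3) if ci[p] != cj[p]]
            paths = []
            for order in itertools.permutations(diff_pos):
                cur = ci
                steps = []
                blocked = False
                for p in order:
                    nxt = cur[:p] + cj[p] + cur[p + 1 :]
                    a_cur, a_nxt = AMINO[_CODON_INDEX[cur]], AMINO[_CODON_INDEX[nxt]]
                    if a_nxt == "*" and nxt != cj:
                        blocked = True
                    steps.append(1.0 if a_cur == a_nxt else 0.0)
                    cur = nxt
                paths.append((blocked, steps))
            usable = [s for blocked, s in paths if not blocked] or [s for _, s in paths]
            sd = sum(sum(s) for s in usable) / len(usable)
            syn_d[i, j] = sd
            nonsyn_d[i, j] = len(diff_pos) - sd
    return syn_d, nonsyn_d


SYN_SITES = _build_site_fractions()
SYN_DIFF, NONSYN_DIFF = _build_pathway_tables()
STOP_IDX = np.array([i for i in range(64) if AMINO[i] == "*"])


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    n_sites: float
    s_sites: float
    nonsyn_diffs: float
    syn_diffs: float
    n_codons: int
    saturated_ka: bool = False
    saturated_ks: bool = False


_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i
_BASE_LUT[ord("U")] = _BASE_LUT[ord("u")] = _BASE_LUT[ord("T")]


def encode_cds(seq: str) -> np.ndarray:
    """Codon-index array for a CDS; codons with gaps/ambiguity become -1."""
    if len(seq) % 3:
        raise ValueError("CDS length must be divisible by 3")
    arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    codons = arr.reshape(-1, 3)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    idx[(codons < 0).any(axis=1)] = -1
    return idx


#: proportions this close to 3/4 are saturated (guards float ties at p = 3/4)
_SATURATION_EPS = 1e-12


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75 - _SATURATION_EPS:
        return math.inf, True
    if p <= 0:
        return 0.0, False
    return -0.75 * math.log(1 - 4 * p / 3), False


def ng86_kaks(cds_a: str | np.ndarray, cds_b: str | np.ndarray) -> KaKsResult:
    """NG86 Ka/Ks for one pre-aligned, equal-length codon sequence pair.

    Codon columns where either sequence has a gap, an ambiguous base or a stop
    codon are dropped pairwise.  ``ratio`` is NaN when Ks = 0 or saturated.
    """
    a = encode_cds(cds_a) if isinstance(cds_a, str) else np.asarray(cds_a)
    b = encode_cds(cds_b) if isinstance(cds_b, str) else np.asarray(cds_b)
    if a.shape != b.shape:
        raise ValueError("sequence lengths differ")
    keep = (a >= 0) & (b >= 0) & (AMINO[a] != "*") & (AMINO[b] != "*")
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no comparable codons after filtering")
    s_sites = float((SYN_SITES[a].sum() + SYN_SITES[b].sum()) / 2)
    n_sites = 3.0 * a.size - s_sites
    sd = float(SYN_DIFF[a, b].sum())
    nd = float(NONSYN_DIFF[a, b].sum())
    ks, sat_s = _jukes_cantor(sd / s_sites if s_sites > 0 else 0.0)
    ka, sat_n = _jukes_cantor(nd / n_sites if n_sites > 0 else 0.0)
    if ks == 0 or math.isinf(ks):
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        n_sites=n_sites,
        s_sites=s_sites,
        nonsyn_diffs=nd,
        syn_diffs=sd,
        n_codons=int(a.size),
        saturated_ka=sat_n,
        saturated_ks=sat_s,
    )


def batch_ng86(arr_a: np.ndarray, arr_b: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised NG86 over many equal-length pairs.

    ``arr_a``/``arr_b`` are (n_pairs, n_codons) codon-index arrays.  Returns
    arrays ka, ks, ratio (NaN where undefined or saturated).
    """
    valid = (arr_a >= 0) & (arr_b >= 0) & (AMINO[np.clip(arr_a, 0, 63)] != "*") & (
        AMINO[np.clip(arr_b, 0, 63)] != "*"
    )
    a = np.where(valid, arr_a, 0)
    b = np.where(valid, arr_b, 0)
    syn_a = np.where(valid, SYN_SITES[a], 0.0).sum(axis=1)
    syn_b = np.where(valid, SYN_SITES[b], 0.0).sum(axis=1)
    s_sites = (syn_a + syn_b) / 2
    n_sites = 3.0 * valid.sum(axis=1) - s_sites
    sd = np.where(valid, SYN_DIFF[a, b], 0.0).sum(axis=1)
    nd = np.where(valid, NONSYN_DIFF[a, b], 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s_sites > 0, sd / s_sites, 0.0)
        pn = np.where(n_sites > 0, nd / n_sites, 0.0)
        sat = 0.75 - _SATURATION_EPS
        ks = np.where(ps < sat, -0.75 * np.log(1 - 4 * np.minimum(ps, sat) / 3), np.nan)
        ka = np.where(pn < sat, -0.75 * np.log(1 - 4 * np.minimum(pn, sat) / 3), np.nan)
        ratio = np.where((ks > 0) & np.isfinite(ks), ka / ks, np.nan)
    return {"ka": ka, "ks": ks, "ratio": ratio, "s_sites": s_sites, "n_sites": n_sites}


# ---------------------------------------------------------------------------
# Block Ks summaries
# ---------------------------------------------------------------------------


def block_ks(block, kaks: Mapping[tuple[str, str], KaKsResult]) -> float | None:
    """Median of the finite pair Ks values of a block; stored on the block.

    Returns None (and stores None) when every pair is saturated or missing,
    which flags the block for exclusion from mixture fitting.
    """
    values = []
    for p in block.pairs:
        res = kaks.get((p.gene_a, p.gene_b))
        ks = getattr(res, "ks", res)
        if ks is not None and math.isfinite(ks):
            values.append(ks)
    block.median_ks = float(np.median(values)) if values else None
    return block.median_ks


# ---------------------------------------------------------------------------
# Gaussian mixture on Ks
# ---------------------------------------------------------------------------


@dataclass
class KsMixtureModel:
    """1-D Gaussian mixture over block Ks values, components sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int
    loglik_history: list[float] = field(default_factory=list)
    converged: bool = False

    def posterior(self, x) -> np.ndarray:
        """Component responsibilities for value(s) x, shape (..., k)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = self.weights * _normpdf(x[:, None], self.means, self.sds)
        return dens / dens.sum(axis=1, keepdims=True)

    @property
    def bic(self) -> float:
        return (3 * self.k - 1) * math.log(self.n) - 2 * self.loglik


def _normpdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def fit_ks_mixture(
    ks_values: Sequence[float],
    k: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    ks_cap: float = 3.0,
    max_restarts: int = 5,
) -> KsMixtureModel:
    """Fit a k-component Gaussian mixture to Ks values by EM.

    Values outside (0, ks_cap] or non-finite are excluded (Ks above the cap is
    treated as saturated).  Initialisation splits the sorted sample into k
    equal quantile chunks; a degenerate component (sd < 1e-4) triggers a
    perturbed restart, up to ``max_restarts``.
    """
    x = np.asarray(ks_values, dtype=float)
    x = x[np.isfinite(x) & (x > 0) & (x <= ks_cap)]
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} usable Ks values, got {x.size}")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            return _em_once(x, k, rng, max_iter, tol, perturb=attempt > 0)
        except _DegenerateComponent as err:
            last_err = err
            logger.info("EM restart %d after degenerate component", attempt + 1)
    raise RuntimeError(f"EM failed after {max_restarts} restarts") from last_err


class _DegenerateComponent(RuntimeError):
    pass


def _em_once(x, k, rng, max_iter, tol, perturb):
    xs = np.sort(x)
    chunks = np.array_split(xs, k)
    means = np.array([c.mean() for c in chunks])
    sds = np.array([max(c.std(), 1e-3) for c in chunks])
    weights = np.array([len(c) / len(x) for c in chunks])
    if perturb:
        means = means * rng.uniform(0.8, 1.2, size=k)
        sds = sds * rng.uniform(0.8, 1.2, size=k)
    history: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = weights * _normpdf(x[:, None], means, sds)
        total = dens.sum(axis=1)
        loglik = float(np.log(total).sum())
        history.append(loglik)
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        sds = np.sqrt((resp * (x[:, None] - means) ** 2).sum(axis=0) / nk)
        if (sds < 1e-4).any():
            raise _DegenerateComponent("component variance collapsed")
        if loglik - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = loglik
    order = np.argsort(means)
    return KsMixtureModel(
        k=k,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=history[-1],
        n=len(x),
        loglik_history=history,
        converged=converged,
    )


def ks_mixture_bic(ks_values, k_range=range(1, 5), seed: int = 0) -> dict[int, float]:
    """BIC per component count, for model-order reporting."""
    out = {}
    for k in k_range:
        try:
            out[k] = fit_ks_mixture(ks_values, k=k, seed=seed).bic
        except (ValueError, RuntimeError):
            out[k] = math.nan
    return out


def classify_blocks_by_ks(
    blocks,
    model: KsMixtureModel,
    ancient_component: int | None = None,
    ks_interval: tuple[float, float] | None = None,
):
    """Split blocks into (recent, ancient) by their median Ks.

    Default rule: a block is ancient when the posterior probability of the
    ancient mixture component (highest mean unless given) exceeds 0.5.  When
    ``ks_interval`` is supplied, a hard Ks window is used instead.  Blocks
    without a median Ks are excluded with a warning.
    """
    if ancient_component is None:
        ancient_component = int(np.argmax(model.means))
    recent, ancient = [], []
    skipped = 0
    for b in blocks:
        if b.median_ks is None:
            skipped += 1
            continue
        if ks_interval is not None:
            is_ancient = ks_interval[0] <= b.median_ks <= ks_interval[1]
        else:
            is_ancient = model.posterior(b.median_ks)[0, ancient_component] > 0.5
        (ancient if is_ancient else recent).append(b)
    if skipped:
        logger.warning("%d block(s) without median Ks excluded from dating", skipped)
    return recent, ancient
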