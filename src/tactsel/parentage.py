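"""Microsatellite locus QC and likelihood-based paternity with known dams.

The assignment machinery follows the classic categorical-allocation scheme:
per-locus likelihood ratios comparing "candidate is the sire" against
"a random male from the allele-frequency distribution is the sire", summed
over loci into a LOD score; the gap (delta) between the two best candidates
is thresholded against critical values obtained by simulation at the desired
confidence levels.

Genotyping error enters through a simple mixture: with probability
(1 - e)**2 the observed offspring genotype is the true one, otherwise it is
treated as a random draw from Hardy-Weinberg genotype frequencies.  This is
an approximation to the full error-integrated likelihood of Marshall et al.;
it keeps every score hand-computable while preserving the key behavior that
a single Mendelian mismatch is fatal only when e = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import MISSING
from .datatypes import GenotypeTable

__all__ = [
    "LocusFrequencies",
    "allele_frequencies",
    "heterozygosity",
    "hwe_test",
    "exact_hwe_two_allele",
    "ld_test",
    "null_allele_estimate",
    "exclusion_probability",
    "locus_qc",
    "lod_score",
    "PaternityAssignment",
    "assign_paternity",
    "confidence_simulation",
    "filter_dam_mismatches",
    "fitness_from_assignments",
]


# ---------------------------------------------------------------------------
# allele frequencies and locus QC


@dataclass
class LocusFrequencies:
    """Allele sizes (sorted) and relative frequencies for one locus."""

    sizes: np.ndarray
    freqs: np.ndarray

    def lookup(self, alleles: np.ndarray) -> np.ndarray:
        """Frequency of each allele size; 0.0 for sizes absent from the table
        (and for the MISSING sentinel)."""
        alleles = np.asarray(alleles)
        pos = np.searchsorted(self.sizes, alleles)
        pos = np.clip(pos, 0, len(self.sizes) - 1)
        hit = self.sizes[pos] == alleles
        return np.where(hit, self.freqs[pos], 0.0)


def _nonmissing(calls: np.ndarray) -> np.ndarray:
    return calls[(calls != MISSING).all(axis=1)]


def allele_frequencies(table: GenotypeTable) -> dict[str, LocusFrequencies]:
    """Per-locus allele frequencies = allele counts / non-missing copies.

    Loci with no non-missing genotypes are excluded (flagged by absence).
    """
    out: dict[str, LocusFrequencies] = {}
    for locus, calls in table.calls.items():
        obs = _nonmissing(calls)
        if len(obs) == 0:
            continue
        sizes, counts = np.unique(obs.ravel(), return_counts=True)
        out[locus] = LocusFrequencies(
            sizes=sizes, freqs=counts / counts.sum()
        )
    return out


def heterozygosity(calls: np.ndarray) -> tuple[float, float]:
    """(observed, expected) heterozygosity from one locus's genotype calls.

    Expected heterozygosity is Nei's gene diversity 1 - sum(p_i^2) computed
    from the same individuals.
    """
    obs = _nonmissing(calls)
    if len(obs) == 0:
        return math.nan, math.nan
    ho = float(np.mean(obs[:, 0] != obs[:, 1]))
    _, counts = np.unique(obs.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = float(1.0 - np.sum(p**2))
    return ho, he


def null_allele_estimate(calls: np.ndarray) -> float:
    """Null-allele frequency r = (He - Ho) / (1 + He), floored at 0
    (Brookfield 1996, estimator 1)."""
    ho, he = heterozygosity(calls)
    if math.isnan(ho):
        return math.nan
    return max(0.0, (he - ho) / (1.0 + he))


def exclusion_probability(freqs: LocusFrequencies) -> float:
    """Probability of excluding a random non-sire when the dam is known
    (Jamieson & Taylor 1997, second-parent formula)."""
    p = freqs.freqs
    a2, a3, a4, a5 = (np.sum(p**k) for k in (2, 3, 4, 5))
    return float(
        1 - 2 * a2 + a3 + 2 * a4 - 3 * a5 - 2 * a2**2 + 3 * a2 * a3
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Markov chain over genotype tables)


def _table_logprob(genos: list[tuple[int, int]]) -> float:
    """Variable part of log P(genotype table | allele counts) under HWE:
    h*ln2 - sum(ln n_g!).  Constant terms cancel along the chain."""
    counts: dict[tuple[int, int], int] = {}
    h = 0
    for g in genos:
        counts[g] = counts.get(g, 0) + 1
        if g[0] != g[1]:
            h += 1
    s = sum(gammaln(c + 1) for c in counts.values())
    return h * math.log(2.0) - s


def hwe_test(
    calls: np.ndarray,
    dememorization: int = 1_000,
    batches: int = 5_000,
    iter_per_batch: int = 1_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test p-value.

    A Metropolis chain walks over genotype tables with the observed allele
    counts fixed, proposing swaps of one allele between two individuals
    (Guo & Thompson-style switch).  p is the fraction of sampled tables whose
    conditional probability is <= the observed table's.

    Returns NaN for monomorphic loci (the test is undefined).
    """
    obs = _nonmissing(calls)
    n = len(obs)
    if n == 0:
        raise ValueError("no non-missing genotypes")
    sizes = np.unique(obs.ravel())
    if len(sizes) < 2:
        return math.nan

    rng = np.random.default_rng(seed)
    remap = {s: i for i, s in enumerate(sizes)}
    # ordered (slot-level) allele assignments: under HWE conditional on
    # allele counts, every arrangement of the 2n allele copies over the n
    # genotype slots is equally likely, and a slot swap is a symmetric
    # proposal on that uniform target -- so every swap is accepted and the
    # induced distribution over genotype-count tables is exactly
    # P(table) proportional to 2^h / prod n_g!
    genos = [[remap[a], remap[b]] for a, b in obs.tolist()]
    counts: dict[tuple[int, int], int] = {}
    h = 0
    for a, b in genos:
        g = (a, b) if a <= b else (b, a)
        counts[g] = counts.get(g, 0) + 1
        if a != b:
            h += 1
    log2 = math.log(2.0)
    lgamma = math.lgamma
    logpi = h * log2 - sum(lgamma(c + 1) for c in counts.values())
    logpi_obs = logpi

    total_steps = dememorization + batches * iter_per_batch
    pairs = rng.integers(0, n, size=(total_steps, 2))
    slots = rng.integers(0, 2, size=(total_steps, 2))

    n_le = 0
    n_samples = 0
    for step in range(total_steps):
        u, v = pairs[step]
        if u != v:
            gu, gv = genos[u], genos[v]
            a, b = slots[step]
            x, y = gu[a], gv[b]
            if x != y:
                old_u = (gu[0], gu[1]) if gu[0] <= gu[1] else (gu[1], gu[0])
                old_v = (gv[0], gv[1]) if gv[0] <= gv[1] else (gv[1], gv[0])
                gu[a], gv[b] = y, x
                new_u = (gu[0], gu[1]) if gu[0] <= gu[1] else (gu[1], gu[0])
                new_v = (gv[0], gv[1]) if gv[0] <= gv[1] else (gv[1], gv[0])
                # incremental update of log pi = h ln2 - sum ln n_g!
                # (sequential removals then additions keep the counts right
                # even when genotype classes coincide)
                cu = counts[old_u]
                counts[old_u] = cu - 1
                cv = counts[old_v]
                counts[old_v] = cv - 1
                c1 = counts.get(new_u, 0)
                counts[new_u] = c1 + 1
                c2 = counts.get(new_v, 0)
                counts[new_v] = c2 + 1
                dh = (
                    (new_u[0] != new_u[1])
                    + (new_v[0] != new_v[1])
                    - (old_u[0] != old_u[1])
                    - (old_v[0] != old_v[1])
                )
                logpi += (
                    dh * log2
                    + math.log(cu) + math.log(cv)
                    - math.log(c1 + 1) - math.log(c2 + 1)
                )
        if step >= dememorization:
            n_samples += 1
            if logpi <= logpi_obs + 1e-9:
                n_le += 1
    return n_le / n_samples


def exact_hwe_two_allele(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Full-enumeration exact HWE test for a two-allele locus (conditional
    on allele counts; p = total probability of tables no more probable than
    the observed one).  Used as an independent oracle for the chain."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    parity = n_a % 2

    def logprob(nab: int) -> float:
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        if naa < 0 or nbb < 0:
            return -math.inf
        return (
            nab * math.log(2.0)
            - math.lgamma(naa + 1)
            - math.lgamma(nab + 1)
            - math.lgamma(nbb + 1)
        )

    support = [k for k in range(parity, min(n_a, 2 * n - n_a) + 1, 2)]
    logs = np.array([logprob(k) for k in support])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    p_obs = probs[support.index(n_ab)]
    return float(probs[probs <= p_obs + 1e-12].sum())


# ---------------------------------------------------------------------------
# linkage disequilibrium (genotypic association) test


def ld_test(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    n_perm: int = 2_000,
    seed: int = 0,
) -> float:
    """Permutation test of genotypic association between two loci.

    The statistic is the Pearson chi-square of the genotype-class
    contingency table; the null is generated by permuting locus B's
    genotypes across individuals.  Returns NaN if either locus is
    monomorphic among jointly typed individuals.
    """
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    ok = (calls_a != MISSING).all(axis=1) & (calls_b != MISSING).all(axis=1)
    a, b = calls_a[ok], calls_b[ok]
    n = len(a)
    if n == 0:
        raise ValueError("no jointly typed individuals")

    def classes(c: np.ndarray) -> np.ndarray:
        _, inv = np.unique(c, axis=0, return_inverse=True)
        return inv

    ia, ib = classes(a), classes(b)
    ka, kb = ia.max() + 1, ib.max() + 1
    if ka < 2 or kb < 2:
        return math.nan

    def chi2(x: np.ndarray, y: np.ndarray) -> float:
        tab = np.zeros((ka, kb))
        np.add.at(tab, (x, y), 1.0)
        exp = np.outer(tab.sum(1), tab.sum(0)) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0)
        return float(cells.sum())

    obs = chi2(ia, ib)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if chi2(ia, rng.permutation(ib)) >= obs - 1e-12:
            exceed += 1
    return exceed / n_perm


def locus_qc(
    table: GenotypeTable,
    hwe_params: tuple[int, int, int] = (1_000, 5_000, 1_000),
    ld_permutations: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """QC summary per locus over the adult samples: Ho, He, HWE p, null
    allele estimate, exclusion probability, plus pairwise LD p-values."""
    adults = table.subset(np.array([r != "offspring" for r in table.roles]))
    freqs = allele_frequencies(adults)
    demem, batches, ipb = hwe_params
    rows = []
    loci = adults.loci
    for i, locus in enumerate(loci):
        calls = adults.calls[locus]
        ho, he = heterozygosity(calls)
        row = {
            "locus": locus,
            "n_typed": int((calls != MISSING).all(axis=1).sum()),
            "n_alleles": len(freqs[locus].sizes) if locus in freqs else 0,
            "Ho": ho,
            "He": he,
            "hwe_p": hwe_test(calls, demem, batches, ipb, seed=seed + i),
            "null_freq": null_allele_estimate(calls),
            "exclusion_prob": (
                exclusion_probability(freqs[locus]) if locus in freqs else math.nan
            ),
        }
        for j, other in enumerate(loci):
            if j <= i:
                continue
            row[f"ld_p_{other}"] = ld_test(
                calls, adults.calls[other], n_perm=ld_permutations,
                seed=seed + 1000 + 31 * i + j,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOD scores and assignment


def _l1_l2_locus(
    off: np.ndarray,
    dam: np.ndarray,
    cand: np.ndarray,
    freqs: LocusFrequencies,
    error_rate: float,
) -> tuple[np.ndarray, float] | None:
    """Per-locus likelihoods for every candidate sire.

    Returns (L1 array over candidates, L2 scalar), or None when the locus is
    uninformative for this offspring (missing calls, or zero denominator).
    Candidates missing at this locus get L1 = L2 (zero LOD contribution).
    """
    if MISSING in off or MISSING in dam:
        return None
    o1, o2 = int(off[0]), int(off[1])
    het = o1 != o2
    f_o1, f_o2 = (float(x) for x in freqs.lookup(np.array([o1, o2])))

    # T2: P(offspring | dam, random sire from freqs)
    t2 = 0.0
    for dm in (int(dam[0]), int(dam[1])):
        if dm == o1:
            t2 += 0.5 * f_o2
        if dm == o2 and het:
            t2 += 0.5 * f_o1
    # T1 per candidate: average over dam allele x candidate allele
    cand = np.asarray(cand)
    t1 = np.zeros(len(cand))
    for dm in (int(dam[0]), int(dam[1])):
        for slot in (0, 1):
            sp = cand[:, slot]
            match = ((dm == o1) & (sp == o2)) | ((dm == o2) & (sp == o1))
            t1 += 0.25 * match
    p_hw = 2.0 * f_o1 * f_o2 if het else f_o1 * f_o1
    keep = (1.0 - error_rate) ** 2
    l1 = keep * t1 + (1.0 - keep) * p_hw
    l2 = keep * t2 + (1.0 - keep) * p_hw
    if l2 <= 0.0:
        return None
    cand_missing = (cand == MISSING).any(axis=1)
    l1 = np.where(cand_missing, l2, l1)
    return l1, l2


def lod_score(
    offspring: dict[str, np.ndarray],
    dam: dict[str, np.ndarray],
    candidate: dict[str, np.ndarray],
    allele_freqs: dict[str, LocusFrequencies],
    error_rate: float = 0.0,
) -> float:
    """LOD = sum over loci of ln L(offspring | dam, candidate) /
    L(offspring | dam, random male).

    Inputs are per-locus genotype mappings (locus -> length-2 array).  Loci
    missing in any of the three individuals, or absent from the frequency
    table, are skipped.  A Mendelian mismatch with e = 0 gives -inf.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    total = 0.0
    used = 0
    for locus, freqs in allele_freqs.items():
        if locus not in offspring or locus not in dam or locus not in candidate:
            continue
        res = _l1_l2_locus(
            np.asarray(offspring[locus]),
            np.asarray(dam[locus]),
            np.asarray(candidate[locus]).reshape(1, 2),
            freqs,
            error_rate,
        )
        if res is None:
            continue
        l1, l2 = res
        used += 1
        with np.errstate(divide="ignore"):
            total += float(np.log(l1[0]) - np.log(l2))
    if used == 0:
        raise ValueError("no loci jointly typed")
    return total


@dataclass
class PaternityAssignment:
    offspring_id: str
    dam_id: str | None
    sire_id: str | None
    lod: float
    delta: float
    confidence: str  # strict | relaxed | unassigned
    loci_compared: int
    mismatches: int
    note: str = ""


def _phw(off: np.ndarray, freqs: LocusFrequencies) -> float:
    o1, o2 = int(off[0]), int(off[1])
    f1, f2 = (float(x) for x in freqs.lookup(np.array([o1, o2])))
    return 2.0 * f1 * f2 if o1 != o2 else f1 * f1


def assign_paternity(
    table: GenotypeTable,
    allele_freqs: dict[str, LocusFrequencies],
    error_rate: float = 0.01,
    strict_delta: float = 0.0,
    relaxed_delta: float = 0.0,
    min_typed_loci: int = 2,
) -> list[PaternityAssignment]:
    """Rank every candidate sire by LOD for each offspring with a known dam.

    delta = LOD1 - max(LOD2, 0), so a lone candidate still needs a positive
    LOD to be assigned.  Exact ties at rank 1 are left unassigned
    (conservative).  Offspring typed at fewer than ``min_typed_loci`` loci
    are left unassigned with a note.
    """
    sires = table.by_role("sire")
    dams = table.by_role("dam")
    dam_lookup = {i: k for k, i in enumerate(dams.ids)}
    out: list[PaternityAssignment] = []
    for idx, (oid, role) in enumerate(zip(table.ids, table.roles)):
        if role != "offspring":
            continue
        did = table.dam_ids[idx]
        note = ""
        if did is None or did not in dam_lookup:
            out.append(PaternityAssignment(oid, did, None, math.nan, math.nan,
                                           "unassigned", 0, 0, "no known dam"))
            continue
        off_calls = {loc: table.calls[loc][idx] for loc in table.loci}
        dam_calls = {loc: dams.calls[loc][dam_lookup[did]] for loc in table.loci}
        typed = sum(
            1 for loc in allele_freqs
            if loc in off_calls
            and MISSING not in off_calls[loc]
            and MISSING not in dam_calls[loc]
        )
        if typed < min_typed_loci:
            out.append(PaternityAssignment(oid, did, None, math.nan, math.nan,
                                           "unassigned", typed, 0,
                                           "too few typed loci"))
            continue
        lods = np.zeros(len(sires))
        mism = np.zeros(len(sires), dtype=int)
        used = 0
        keep = (1.0 - error_rate) ** 2
        for locus, freqs in allele_freqs.items():
            res = _l1_l2_locus(
                off_calls[locus], dam_calls[locus],
                sires.calls[locus], freqs, error_rate,
            )
            if res is None:
                continue
            l1, l2 = res
            used += 1
            with np.errstate(divide="ignore"):
                lods += np.log(l1) - np.log(l2)
            cand_missing = (sires.calls[locus] == MISSING).any(axis=1)
            t1 = (l1 - (1.0 - keep) * _phw(off_calls[locus], freqs)) / max(keep, 1e-300)
            mism += (t1 <= 1e-12) & ~cand_missing
        if used == 0:
            out.append(PaternityAssignment(oid, did, None, math.nan, math.nan,
                                           "unassigned", 0, 0,
                                           "no informative loci"))
            continue
        order = np.argsort(-lods, kind="stable")
        lod1 = lods[order[0]]
        lod2 = lods[order[1]] if len(lods) > 1 else -math.inf
        tie = len(lods) > 1 and abs(lod1 - lod2) <= 1e-12 and math.isfinite(lod1)
        delta = lod1 - max(lod2, 0.0)
        if tie:
            conf, sire_id, note = "unassigned", None, "tied top LOD"
        elif not math.isfinite(lod1) or lod1 <= 0.0:
            conf, sire_id = "unassigned", None
        elif delta >= strict_delta:
            conf, sire_id = "strict", sires.ids[order[0]]
        elif delta >= relaxed_delta:
            conf, sire_id = "relaxed", sires.ids[order[0]]
        else:
            conf, sire_id = "unassigned", None
        out.append(PaternityAssignment(
            oid, did, sire_id,
            float(lod1), float(max(delta, 0.0)) if math.isfinite(delta) else 0.0,
            conf, used, int(mism[order[0]]), note,
        ))
    return out


# ---------------------------------------------------------------------------
# confidence simulation (delta thresholds)


def _hw_genotypes(rng, freqs: LocusFrequencies, shape) -> np.ndarray:
    """Random Hardy-Weinberg genotypes as allele sizes, shape (..., 2)."""
    idx = rng.choice(len(freqs.sizes), size=tuple(shape) + (2,), p=freqs.freqs)
    return freqs.sizes[idx]


def confidence_simulation(
    allele_freqs: dict[str, LocusFrequencies],
    n_offspring: int = 10_000,
    n_candidates: int = 92,
    prop_sampled: float = 0.87,
    prop_typed: float = 1.0,
    error_rate: float = 0.01,
    levels: tuple[float, ...] = (0.95, 0.80),
    seed: int = 0,
) -> dict:
    """Critical delta values by simulation.

    Offspring are generated from random dam x sire pairs drawn from the
    allele frequencies; the true sire appears in the sampled candidate pool
    with probability ``prop_sampled``; each genotype is typed with
    probability ``prop_typed`` and each observed allele is replaced by a
    random allele at ``error_rate``.  For each confidence level the
    threshold is the smallest delta at which the proportion of correct
    assignments among candidate assignments reaches the level.

    Returns {"thresholds": {level: delta}, "assignment_rate": {level: rate},
    "n_scored": int}.
    """
    for level in levels:
        if not (0.0 < level < 1.0):
            raise ValueError("confidence levels must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pool = n_candidates
    loci = list(allele_freqs)

    # genotypes: dams, true sires, unrelated candidates
    deltas = np.full(n_offspring, -math.inf)
    correct = np.zeros(n_offspring, dtype=bool)
    scorable = np.zeros(n_offspring, dtype=bool)

    lods = np.zeros((n_offspring, n_pool))
    informative = np.zeros(n_offspring, dtype=int)
    sampled = rng.random(n_offspring) < prop_sampled  # true sire in pool?

    for locus in loci:
        freqs = allele_freqs[locus]
        dam_g = _hw_genotypes(rng, freqs, (n_offspring,))
        sire_g = _hw_genotypes(rng, freqs, (n_offspring,))
        cand_g = _hw_genotypes(rng, freqs, (n_offspring, n_pool))
        # slot 0 of the candidate pool holds the true sire when sampled
        cand_g[sampled, 0] = sire_g[sampled]
        off = np.stack(
            [
                np.take_along_axis(dam_g, rng.integers(0, 2, (n_offspring, 1)), 1)[:, 0],
                np.take_along_axis(sire_g, rng.integers(0, 2, (n_offspring, 1)), 1)[:, 0],
            ],
            axis=1,
        )

        def corrupt(g: np.ndarray) -> np.ndarray:
            if error_rate > 0:
                err = rng.random(g.shape) < error_rate
                repl = freqs.sizes[
                    rng.choice(len(freqs.sizes), size=g.shape, p=freqs.freqs)
                ]
                g = np.where(err, repl, g)
            return np.sort(g, axis=-1)

        dam_o, off_o, cand_o = corrupt(dam_g), corrupt(off), corrupt(cand_g)
        if prop_typed < 1.0:
            untyped = rng.random(n_offspring) >= prop_typed
        else:
            untyped = np.zeros(n_offspring, dtype=bool)

        keep = (1.0 - error_rate) ** 2
        for i in range(n_offspring):
            if untyped[i]:
                continue
            res = _l1_l2_locus(off_o[i], dam_o[i], cand_o[i], freqs, error_rate)
            if res is None:
                continue
            l1, l2 = res
            with np.errstate(divide="ignore"):
                lods[i] += np.log(l1) - np.log(l2)
            informative[i] += 1

    for i in range(n_offspring):
        if informative[i] == 0:
            continue
        row = lods[i]
        order = np.argsort(-row, kind="stable")
        lod1 = row[order[0]]
        lod2 = row[order[1]] if n_pool > 1 else -math.inf
        if not math.isfinite(lod1) or lod1 <= 0.0:
            continue
        if n_pool > 1 and abs(lod1 - lod2) <= 1e-12:
            continue
        scorable[i] = True
        deltas[i] = lod1 - max(lod2, 0.0)
        correct[i] = sampled[i] and order[0] == 0

    d = deltas[scorable]
    c = correct[scorable]
    thresholds: dict[float, float] = {}
    rates: dict[float, float] = {}
    if len(d) == 0:
        return {"thresholds": {lv: math.inf for lv in levels},
                "assignment_rate": {lv: 0.0 for lv in levels},
                "n_scored": 0}
    order = np.argsort(-d, kind="stable")
    d_sorted = d[order]
    acc = np.cumsum(c[order]) / np.arange(1, len(d) + 1)
    for level in levels:
        ok = np.nonzero(acc >= level)[0]
        if len(ok) == 0:
            thresholds[level] = math.inf
            rates[level] = 0.0
        else:
            # most inclusive cutoff keeping accuracy >= level; if accuracy
            # holds over the whole sample the critical delta collapses to 0
            j = int(ok[-1])
            if j == len(d_sorted) - 1:
                thresholds[level] = 0.0
            else:
                thresholds[level] = float(
                    max(0.0, 0.5 * (d_sorted[j] + d_sorted[j + 1]))
                )
            rates[level] = (j + 1) / n_offspring
    return {
        "thresholds": thresholds,
        "assignment_rate": rates,
        "n_scored": int(scorable.sum()),
    }


# ---------------------------------------------------------------------------
# filtering and fitness


def filter_dam_mismatches(
    table: GenotypeTable, max_mismatch_loci: int = 0
) -> tuple[GenotypeTable, list[str]]:
    """Drop offspring incompatible with their known dam.

    An offspring mismatches its dam at a locus when both are typed there and
    they share no allele.  Offspring with more than ``max_mismatch_loci``
    mismatching loci (or whose dam is untyped everywhere they are typed) are
    removed before assignment; the dropped ids are returned for logging.
    """
    dams = table.by_role("dam")
    dam_lookup = {i: k for k, i in enumerate(dams.ids)}
    keep = np.ones(len(table), dtype=bool)
    dropped: list[str] = []
    for idx, (oid, role) in enumerate(zip(table.ids, table.roles)):
        if role != "offspring":
            continue
        did = table.dam_ids[idx]
        if did is None or did not in dam_lookup:
            continue
        drow = dam_lookup[did]
        mism = 0
        compared = 0
        for locus in table.loci:
            og = table.calls[locus][idx]
            dg = dams.calls[locus][drow]
            if MISSING in og or MISSING in dg:
                continue
            compared += 1
            if not (og[0] in dg or og[1] in dg):
                mism += 1
        if compared == 0 or mism > max_mismatch_loci:
            keep[idx] = False
            dropped.append(oid)
    return table.subset(keep), dropped


def fitness_from_assignments(
    assignments: list[PaternityAssignment],
    all_male_ids: list[str],
    confidences: tuple[str, ...] = ("strict", "relaxed"),
) -> pd.DataFrame:
    """Absolute fitness = number of confidently assigned offspring per male;
    males with no assignments appear with fitness zero."""
    counts = {m: 0 for m in all_male_ids}
    for a in assignments:
        if a.confidence in confidences and a.sire_id is not None:
            if a.sire_id not in counts:
                raise KeyError(f"assigned sire {a.sire_id} not in male list")
            counts[a.sire_id] += 1
    return pd.DataFrame(
        {"id": list(counts), "n_offspring": list(counts.values())}
    )
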