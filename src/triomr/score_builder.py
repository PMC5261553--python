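"""Weighted BMI allele scores and maternal haplotype scores.

A weighted allele score summarises a person's burden of BMI-raising
alleles across a panel of unlinked SNPs:

    weighted score = sum_j w_j * d_j

where ``d_j`` is the dosage (0, 1 or 2; fractional for imputed data) of
the effect allele at SNP *j* and ``w_j`` is the per-allele effect size of
that SNP on BMI from published GWAS.  The score can be rescaled to the
average-allele-count scale,

    rescaled score = weighted score * n_available / sum of available weights,

which makes it interpretable as a number of BMI-increasing alleles.

For mothers with phased genotypes and known transmission, the weighted
score partitions exactly into a transmitted-haplotype score and a
non-transmitted-haplotype score.  The non-transmitted score is the basis
of a transmission-free sensitivity analysis: those alleles can affect
the offspring only through the maternal phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PANEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "weight", "freq"]


@dataclass
class SNPPanel:
    """Per-SNP effect allele, GWAS weight and effect-allele frequency.

    Weights are per-allele beta coefficients (SD of BMI per effect
    allele) from the published GWAS; frequencies are effect-allele
    frequencies in (0, 1) and are used both by the trio simulator and
    for theoretical score moments.
    """

    snp_id: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    weight: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = list(self.snp_id)
        self.effect_allele = list(self.effect_allele)
        self.other_allele = list(self.other_allele)
        self.weight = np.asarray(self.weight, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        n = len(self.snp_id)
        if n == 0:
            raise ValueError("SNP panel must contain at least one SNP")
        for name, col in (("effect_allele", self.effect_allele),
                          ("other_allele", self.other_allele)):
            if len(col) != n:
                raise ValueError(f"panel column {name!r} has length {len(col)}, expected {n}")
        if self.weight.shape != (n,) or self.freq.shape != (n,):
            raise ValueError("weight and freq must be 1-D arrays matching snp_id")
        if len(set(self.snp_id)) != n:
            raise ValueError("duplicate SNP ids in panel")
        if np.any((self.freq <= 0.0) | (self.freq >= 1.0)):
            bad = [s for s, p in zip(self.snp_id, self.freq) if not 0.0 < p < 1.0]
            raise ValueError(f"effect-allele frequencies must lie in (0,1); offending SNPs: {bad}")
        for s, a, b in zip(self.snp_id, self.effect_allele, self.other_allele):
            if a == b:
                raise ValueError(f"SNP {s}: effect and other allele are identical")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    # Theoretical moments of the weighted score under Hardy-Weinberg
    # proportions with unlinked loci; used by the simulator to put the
    # latent genetic value on a mean-0, variance-1 scale.
    @property
    def score_mean(self) -> float:
        return float(np.sum(2.0 * self.freq * self.weight))

    @property
    def score_var(self) -> float:
        return float(np.sum(self.weight ** 2 * 2.0 * self.freq * (1.0 - self.freq)))

    @property
    def score_sd(self) -> float:
        return float(np.sqrt(self.score_var))

    def subset(self, mask: np.ndarray) -> "SNPPanel":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return SNPPanel(
            [self.snp_id[i] for i in idx],
            [self.effect_allele[i] for i in idx],
            [self.other_allele[i] for i in idx],
            self.weight[idx],
            self.freq[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "weight": self.weight,
            "freq": self.freq,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel file {path} is missing columns {missing}")
        return cls(
            df["snp_id"].astype(str).tolist(),
            df["effect_allele"].astype(str).tolist(),
            df["other_allele"].astype(str).tolist(),
            df["weight"].to_numpy(float),
            df["freq"].to_numpy(float),
        )


def weighted_score(dosages: np.ndarray, panel: SNPPanel) -> np.ndarray | float:
    """Weighted allele score: sum of (GWAS weight x effect-allele dosage).

    ``dosages`` is an array of effect-allele dosages in [0, 2], shaped
    ``(n_snps,)`` for one person or ``(n_people, n_snps)``.  NaN entries
    are treated as missing and skipped; a person with every dosage
    missing gets a NaN score (logged).
    """
    d = np.asarray(dosages, dtype=float)
    scalar = d.ndim == 1
    d = np.atleast_2d(d)
    if d.shape[1] != panel.n_snps:
        raise ValueError(
            f"dosage vector has {d.shape[1]} SNPs but panel has {panel.n_snps}")
    finite = np.isfinite(d)
    with np.errstate(invalid="ignore"):
        if np.any(d[finite] < 0) or np.any(d[finite] > 2):
            raise ValueError("dosages must lie in [0, 2]")
    score = np.where(finite, d * panel.weight, 0.0).sum(axis=1)
    all_missing = ~finite.any(axis=1)
    if all_missing.any():
        log.warning("%d individual(s) have no non-missing dosages; score set to NaN",
                    int(all_missing.sum()))
        score = np.where(all_missing, np.nan, score)
    return float(score[0]) if scalar else score


def rescale_score(weighted, panel: SNPPanel, available: np.ndarray | None = None):
    """Rescale a weighted score to the average-allele-count scale.

    rescaled = weighted * (number of available SNPs) / (sum of their weights),
    where availability is per person (``available`` is a boolean mask of
    shape ``(n_snps,)`` or ``(n_people, n_snps)``; default: all SNPs).
    """
    w = np.asarray(weighted, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    if available is None:
        avail = np.ones((w.shape[0], panel.n_snps), dtype=bool)
    else:
        avail = np.atleast_2d(np.asarray(available, dtype=bool))
        if avail.shape[0] == 1 and w.shape[0] > 1:
            avail = np.broadcast_to(avail, (w.shape[0], panel.n_snps))
    if avail.shape[1] != panel.n_snps:
        raise ValueError("availability mask does not match panel size")
    n_avail = avail.sum(axis=1)
    wsum = (avail * panel.weight).sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("sum of weights of available SNPs must be positive")
    out = w * n_avail / wsum
    return float(out[0]) if scalar else out


def haplotype_scores(hap1: np.ndarray, hap2: np.ndarray,
                     transmitted_index: np.ndarray, panel: SNPPanel):
    """Transmitted and non-transmitted maternal haplotype scores.

    ``hap1``/``hap2`` are phased allele arrays (0/1, effect-allele
    coded) of shape ``(n, n_snps)``; ``transmitted_index`` is 0 where
    hap1 was transmitted to the offspring and 1 where hap2 was.
    Returns ``(transmitted, non_transmitted)`` weighted scores; their
    sum equals the maternal weighted score exactly.
    """
    h1 = np.atleast_2d(np.asarray(hap1))
    h2 = np.atleast_2d(np.asarray(hap2))
    t = np.atleast_2d(np.asarray(transmitted_index))
    if h1.shape != h2.shape or h1.shape != t.shape:
        raise ValueError("haplotype and transmission arrays must share a shape")
    if h1.shape[1] != panel.n_snps:
        raise ValueError("haplotypes do not match panel size")
    for name, a in (("hap1", h1), ("hap2", h2)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(
                f"{name} contains values outside {{0,1}}: haplotype scores require "
                "phased input (use a phased VCF with '|' genotype separators)")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("transmitted_index must be 0 (hap1) or 1 (hap2)")
    trans = np.where(t == 1, h2, h1).astype(float)
    nontrans = np.where(t == 1, h1, h2).astype(float)
    return trans @ panel.weight, nontrans @ panel.weight


def infer_transmission(maternal_h1: np.ndarray, maternal_h2: np.ndarray,
                       paternal_genotype: np.ndarray,
                       offspring_genotype: np.ndarray):
    """Infer which maternal haplotype was transmitted, where unambiguous.

    For homozygous mothers either haplotype label is equivalent (index 0
    returned).  For a heterozygous mother the transmitted allele equals
    offspring genotype minus the paternal transmitted allele, which is
    known when the father is homozygous or when the offspring genotype
    pins it down; the triple het (mother, father and child all
    heterozygous) is ambiguous and marked NaN.  Returns
    ``(transmitted_index, n_ambiguous)``; ambiguous entries are excluded
    from haplotype scores by callers, with the count logged here.
    """
    h1 = np.atleast_2d(np.asarray(maternal_h1, dtype=float))
    h2 = np.atleast_2d(np.asarray(maternal_h2, dtype=float))
    gf = np.atleast_2d(np.asarray(paternal_genotype, dtype=float))
    go = np.atleast_2d(np.asarray(offspring_genotype, dtype=float))
    t = np.zeros_like(h1)
    het_m = h1 != h2
    # father homozygous -> his transmitted allele is gf/2; maternal = go - that
    pat_known = gf != 1
    mat_allele = go - gf / 2.0
    ok = het_m & pat_known
    t[ok & (mat_allele == h2)] = 1.0
    # father het: offspring 0 or 2 pins both transmissions; offspring het is ambiguous
    pat_het = het_m & ~pat_known
    t[pat_het & (go == 2) & (h2 == 1)] = 1.0
    t[pat_het & (go == 0) & (h2 == 0)] = 1.0
    ambiguous = pat_het & (go == 1)
    t[ambiguous] = np.nan
    n_amb = int(ambiguous.sum())
    if n_amb:
        log.info("transmission ambiguous at %d (family, SNP) records; "
                 "excluded from haplotype scores", n_amb)
    return t, n_amb


def cohort_score_table(cohort, panel: SNPPanel) -> pd.DataFrame:
    """Per-person score table for a simulated trio cohort.

    One row per person (mother, father, offspring per family) with
    weighted and rescaled scores; mothers additionally carry transmitted
    and non-transmitted haplotype scores.
    """
    gm = cohort.maternal_genotype
    gf = cohort.paternal_genotype
    go = cohort.offspring_genotype
    wm = weighted_score(gm, panel)
    wf = weighted_score(gf, panel)
    wo = weighted_score(go, panel)
    t_score, nt_score = haplotype_scores(
        cohort.maternal_h1, cohort.maternal_h2,
        cohort.maternal_transmitted_index, panel)
    rows = []
    fam = cohort.family_id
    for role, ids, w in (("mother", cohort.mother_id, wm),
                         ("father", cohort.father_id, wf),
                         ("offspring", cohort.child_id, wo)):
        df = pd.DataFrame({
            "person_id": ids,
            "family_id": fam,
            "role": role,
            "weighted": w,
            "rescaled": rescale_score(w, panel),
            "n_snps": panel.n_snps,
        })
        if role == "mother":
            df["transmitted"] = t_score
            df["non_transmitted"] = nt_score
        else:
            df["transmitted"] = np.nan
            df["non_transmitted"] = np.nan
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out[["person_id", "family_id", "role", "weighted", "rescaled",
                "transmitted", "non_transmitted", "n_snps"]]
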