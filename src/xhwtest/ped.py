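"""Linkage/PED pedigree input and per-locus batch analysis.

The tests assume a sample of mutually independent X chromosomes, so only
genotyped founders (individuals whose parents are absent from the
pedigree) contribute.  PED has no haploid representation: male X
genotypes are conventionally written as a homozygous pair, so a male
record with two identical allele codes counts as one allele, and a male
with two different codes is treated as a genotyping error and excluded
at that marker with a warning.  A record with any missing allele code
(``0``) at a marker is excluded at that marker only.

``analyze_file`` runs every marker through the full battery and writes a
``results.txt``-style delimited table (marker, counts, estimates under
the alternative and each null, statistics, p-values), with the
Bonferroni-adjusted threshold ``alpha / m`` reported in the header.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeCounts, UndefinedStatisticError
from .estimators import EMConfig, fit_h0, fit_h01, fit_h02, fit_h1, rho_moment
from .stats import TestResult, dc_variants, lrt0, lrt1, lrt2, z0, z1, z2
from .bootstrap import BootstrapConfig, bootstrap_pvalue
from .simulate import ALL_TESTS

__all__ = ["PedigreeRecord", "LocusReport", "read_ped", "counts_from_founders",
           "analyze_file"]

MISSING = "0"


@dataclass
class PedigreeRecord:
    """One PED line: ids, sex (1 male / 2 female) and allele-code pairs."""

    family: str
    individual: str
    father: str
    mother: str
    sex: int
    phenotype: str
    genotypes: list[tuple[str, str]]

    @property
    def is_founder(self) -> bool:
        return self.father == MISSING and self.mother == MISSING


@dataclass
class LocusReport:
    """Per-marker results: counts used, fits, statistics, p-values."""

    marker: str
    counts: GenotypeCounts
    m1_allele: Optional[str]
    fits: dict
    results: dict[str, Optional[TestResult]]
    notes: list[str] = field(default_factory=list)


def read_ped(path) -> list[PedigreeRecord]:
    """Parse a whitespace-delimited PED file.

    Six leading columns (family, individual, father, mother, sex,
    phenotype) followed by an even number of allele columns.  Malformed
    lines and unknown sex codes are reported by line number (as warnings)
    and skipped.
    """
    records: list[PedigreeRecord] = []
    n_markers = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2 != 0:
                warnings.warn(f"{path}:{lineno}: malformed line "
                              f"({len(fields)} fields); skipped")
                continue
            try:
                sex = int(fields[4])
            except ValueError:
                sex = -1
            if sex not in (1, 2):
                warnings.warn(f"{path}:{lineno}: unknown sex code "
                              f"{fields[4]!r}; record excluded")
                continue
            alleles = fields[6:]
            geno = [(alleles[i], alleles[i + 1]) for i in range(0, len(alleles), 2)]
            if n_markers is None:
                n_markers = len(geno)
            elif len(geno) != n_markers:
                warnings.warn(f"{path}:{lineno}: expected {n_markers} markers, "
                              f"found {len(geno)}; skipped")
                continue
            records.append(PedigreeRecord(fields[0], fields[1], fields[2],
                                          fields[3], sex, fields[5], geno))
    if not records:
        warnings.warn(f"{path}: no usable records")
    return records


def _founder_calls(records: Sequence[PedigreeRecord], marker: int):
    """(male alleles, female genotype pairs) among genotyped founders."""
    males, females = [], []
    for rec in records:
        if not rec.is_founder:
            continue
        a, b = rec.genotypes[marker]
        if a == MISSING or b == MISSING:
            continue
        if rec.sex == 1:
            if a != b:
                warnings.warn(
                    f"male founder {rec.family}/{rec.individual} heterozygous "
                    f"at marker {marker}; treated as missing")
                continue
            males.append(a)
        else:
            females.append((a, b))
    return males, females


def _choose_m1(males, females) -> Optional[str]:
    """Minor allele among founders; ties broken lexicographically."""
    tally: Counter = Counter(males)
    for a, b in females:
        tally[a] += 1
        tally[b] += 1
    if not tally:
        return None
    if len(tally) > 2:
        raise ValueError(f"more than two alleles at marker: {sorted(tally)}")
    return min(tally, key=lambda al: (tally[al], al))


def counts_from_founders(records: Sequence[PedigreeRecord], marker: int,
                         m1_allele: Optional[str] = None) -> GenotypeCounts:
    """Genotype counts from genotyped founders at one marker.

    M1 defaults to the minor allele among founders (lexicographic
    tie-break); pass ``m1_allele`` to fix the coding.  Swapping the
    coding swaps (n1m, n0m) and (n2f, n0f); all p-values are invariant
    to that swap.
    """
    males, females = _founder_calls(records, marker)
    if m1_allele is None:
        m1_allele = _choose_m1(males, females)
    n1m = sum(1 for a in males if a == m1_allele)
    n2f = sum(1 for a, b in females if a == m1_allele and b == m1_allele)
    n1f = sum(1 for a, b in females if (a == m1_allele) != (b == m1_allele))
    return GenotypeCounts(n1m, len(males) - n1m, n2f, n1f,
                          len(females) - n2f - n1f)


def _analyze_locus(marker, counts, m1, tests, em, boot_b, dc, seedseq):
    fits = {}
    results: dict[str, Optional[TestResult]] = {}
    notes: list[str] = []
    try:
        fits["H1"] = fit_h1(counts, em)
        fits["H0"] = fit_h0(counts)
        fits["H01"] = fit_h01(counts, em)
        fits["H02"] = fit_h02(counts)
    except (ValueError, ZeroDivisionError) as exc:
        notes.append(f"fits unavailable: {exc}")
    try:
        fits["rho_z"] = rho_moment(counts)
    except UndefinedStatisticError:
        fits["rho_z"] = None
    dc_res = None
    boot_seeds = dict(zip(sorted(t for t in tests if t.endswith("b")),
                          seedseq.spawn(sum(t.endswith("b") for t in tests))))
    for name in tests:
        try:
            if name.endswith("b"):
                cfg = BootstrapConfig(B=boot_b, seed=boot_seeds[name],
                                      which=name[:-1])
                results[name] = bootstrap_pvalue(counts, cfg, em, dc=dc)
            elif dc and name in ("LRT0", "LRT1"):
                if dc_res is None:
                    dc_res = dc_variants(counts, em)
                results[name] = dc_res[name]
            else:
                fn = {"Z0": z0, "Z1": z1, "Z2": z2}.get(name)
                if fn is not None:
                    results[name] = fn(counts)
                else:
                    fn = {"LRT0": lrt0, "LRT1": lrt1, "LRT2": lrt2}[name]
                    results[name] = fn(counts, em)
        except (UndefinedStatisticError, ValueError) as exc:
            results[name] = None
            notes.append(f"{name} undefined: {exc}")
    return LocusReport(marker, counts, m1, fits, results, notes)


def analyze_file(path, tests: Sequence[str] = ALL_TESTS, alpha: float = 0.05,
                 boot_b: int = 1000, em: EMConfig = EMConfig(),
                 seed: Optional[int] = None, dc: bool = False,
                 out_path=None, marker_names: Optional[Sequence[str]] = None):
    """Analyze every marker of a PED file; optionally write a results table.

    Returns ``(reports, bonferroni_threshold)``.  Markers where a
    statistic is undefined are flagged in the report, not dropped.  Each
    locus draws its bootstrap streams from its own child of ``seed``, so
    batch results equal independent single-locus runs.
    """
    records = read_ped(path)
    n_markers = len(records[0].genotypes) if records else 0
    if marker_names is None:
        marker_names = [f"M{i + 1}" for i in range(n_markers)]
    root = np.random.SeedSequence(seed)
    children = root.spawn(max(n_markers, 1))
    reports = []
    for j in range(n_markers):
        males, females = _founder_calls(records, j)
        m1 = _choose_m1(males, females)
        counts = counts_from_founders(records, j, m1)
        reports.append(_analyze_locus(marker_names[j], counts, m1, tests, em,
                                      boot_b, dc, children[j]))
    threshold = alpha / n_markers if n_markers else float("nan")
    if out_path is not None:
        _write_results(reports, tests, alpha, threshold, out_path)
    return reports, threshold


def reports_to_frame(reports: Sequence[LocusReport],
                     tests: Sequence[str]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        c = rep.counts
        row = {
            "marker": rep.marker, "M1": rep.m1_allele,
            "n1m": c.n1m, "n0m": c.n0m, "n2f": c.n2f, "n1f": c.n1f,
            "n0f": c.n0f,
        }
        h1 = rep.fits.get("H1")
        if h1 is not None:
            row.update(pm_H1=h1.params_hat.p_m, pf_H1=h1.params_hat.p_f,
                       rho_H1=h1.params_hat.rho)
        h0 = rep.fits.get("H0")
        if h0 is not None:
            row.update(p_H0=h0.params_hat.p_m)
        h01 = rep.fits.get("H01")
        if h01 is not None:
            row.update(p_H01=h01.params_hat.p_m, rho_H01=h01.params_hat.rho)
        h02 = rep.fits.get("H02")
        if h02 is not None:
            row.update(pm_H02=h02.params_hat.p_m, pf_H02=h02.params_hat.p_f)
        row["rho_z"] = rep.fits.get("rho_z")
        for name in tests:
            res = rep.results.get(name)
            row[name] = res.statistic if res is not None else np.nan
            row[f"P_{name}"] = res.p_value if res is not None else np.nan
        row["notes"] = "; ".join(rep.notes)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_results(reports, tests, alpha, threshold, out_path) -> None:
    frame = reports_to_frame(reports, tests)
    with open(out_path, "w") as fh:
        fh.write(f"# markers analyzed: {len(reports)}\n")
        fh.write(f"# significance level: {alpha}\n")
        fh.write(f"# Bonferroni-adjusted threshold: {threshold:.6g}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
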