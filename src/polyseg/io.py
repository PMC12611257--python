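"""Data ingestion, result tables, and multiple-testing output.

Supported inputs per locus:

* VCF with ``GL`` (log10 genotype likelihoods), ``PL`` (phred-scaled), or
  ``AD`` (allele depths, converted to genotype likelihoods through the
  sequencing model of :mod:`polyseg.simulate`); biallelic records only,
  multiallelic records are skipped with a logged reason.  Genotype-field
  arity must match the requested ploidy (for a biallelic locus the VCF
  genotype ordering is dosage-ordered).
* TSV genotype-likelihood matrices (columns ``g0..gK``, natural scale, one
  row per individual, optional ``locus``/``sample`` columns).
* TSV dosage tables (column ``dosage``, one row per individual).

Parents may be given as sample names (their dosages are then called from
their own genotype data and they are excluded from the offspring) or as
explicit integer dosages.

Results are returned as a :class:`pandas.DataFrame` with
Benjamini–Hochberg adjusted q-values across the tested loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .freq import NullModelSpec
from .likelihood import GenotypeCounts, GenotypeLikelihoods
from .lrt import test_locus
from .simulate import SeqParams, genotype_likelihoods_from_reads

logger = logging.getLogger("polyseg")

LN10 = math.log(10.0)

FORMATS = ("vcf-gl", "vcf-pl", "vcf-ad", "tsv-likelihood", "tsv-dosage")

__all__ = ["LocusRecord", "LocusTable", "read_genotype_input", "run_tests",
           "write_vcf_gl", "FORMATS"]


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic locus ready for testing."""

    locus_id: str
    data: object  # GenotypeCounts or GenotypeLikelihoods
    chrom: str = "."
    pos: int = 0
    parent_dosages: tuple | None = None  # called from parent samples, if any


@dataclass
class LocusTable:
    """A batch of loci plus shared sample metadata."""

    loci: list[LocusRecord] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    n_skipped: int = 0


def _resolve_parents(parents, samples):
    """Split a parents option into (sample-name list, explicit dosages)."""
    if parents is None:
        return [], None
    names, dosages = [], []
    for p in parents:
        try:
            dosages.append(int(p))
        except (TypeError, ValueError):
            names.append(str(p))
    if names and dosages:
        raise ValueError("parents must be all sample names or all integer dosages")
    if dosages:
        return [], tuple(dosages)
    missing = [n for n in names if n not in samples]
    if missing:
        raise ValueError(f"parent samples not found: {missing}")
    return names, None


def _vcf_log_gl(variant, fmt, ploidy, seq_params):
    """Natural-log genotype likelihood matrix for one VCF record."""
    if fmt == "vcf-gl":
        gl = variant.format("GL")
        if gl is None:
            raise ValueError("record lacks GL")
        gl = np.asarray(gl, dtype=float)
        if gl.shape[1] != ploidy + 1:
            raise ValueError(
                f"GL arity {gl.shape[1]} does not match ploidy {ploidy}"
            )
        log_g = gl * LN10
    elif fmt == "vcf-pl":
        pl = variant.format("PL")
        if pl is None:
            raise ValueError("record lacks PL")
        pl = np.asarray(pl, dtype=float)
        if pl.shape[1] != ploidy + 1:
            raise ValueError(
                f"PL arity {pl.shape[1]} does not match ploidy {ploidy}"
            )
        log_g = -pl / 10.0 * LN10
    else:  # vcf-ad
        ad = variant.format("AD")
        if ad is None:
            raise ValueError("record lacks AD")
        ad = np.asarray(ad, dtype=float)
        log_g = np.zeros((ad.shape[0], ploidy + 1))
        for i in range(ad.shape[0]):
            ref, alt = ad[i, 0], ad[i, 1]
            if ref < 0 or alt < 0 or np.isnan(ref) or np.isnan(alt):
                continue  # missing -> flat row
            depth = int(ref + alt)
            log_g[i] = genotype_likelihoods_from_reads(
                int(alt), depth, ploidy, seq_params
            )
    # missing entries become flat (uninformative) rows rather than dropping
    bad = ~np.all(np.isfinite(log_g) | np.isinf(log_g), axis=1)
    log_g[bad] = 0.0
    allinf = np.all(np.isinf(log_g), axis=1)
    log_g[allinf] = 0.0
    return log_g


def read_genotype_input(path, fmt, ploidy, parents=None,
                        seq_params: SeqParams | None = None) -> LocusTable:
    """Read per-locus genotype data from VCF or delimited text."""
    if fmt not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {fmt!r}")
    seq_params = seq_params or SeqParams(depth=10)
    if fmt.startswith("vcf"):
        return _read_vcf(path, fmt, ploidy, parents, seq_params)
    return _read_tsv(path, fmt, ploidy, parents)


def _read_vcf(path, fmt, ploidy, parents, seq_params) -> LocusTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    parent_names, parent_dosages = _resolve_parents(parents, samples)
    pidx = [samples.index(n) for n in parent_names]
    oidx = [i for i in range(len(samples)) if i not in pidx]
    table = LocusTable(samples=[samples[i] for i in oidx])
    for variant in vcf:
        lid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            logger.info("skipping %s: multiallelic record", lid)
            table.n_skipped += 1
            continue
        try:
            log_g = _vcf_log_gl(variant, fmt, ploidy, seq_params)
        except ValueError as exc:
            raise ValueError(f"locus {lid}: {exc}") from None
        called = None
        if pidx:
            called = tuple(int(np.argmax(log_g[i])) for i in pidx)
        elif parent_dosages is not None:
            called = parent_dosages
        table.loci.append(
            LocusRecord(
                locus_id=lid,
                data=GenotypeLikelihoods(log_g[oidx]),
                chrom=variant.CHROM,
                pos=variant.POS,
                parent_dosages=called,
            )
        )
    return table


def _read_tsv(path, fmt, ploidy, parents) -> LocusTable:
    df = pd.read_csv(path, sep="\t")
    _, parent_dosages = _resolve_parents(parents, list(df.get("sample", [])))
    groups = df.groupby("locus", sort=False) if "locus" in df.columns else [("locus1", df)]
    table = LocusTable()
    for lid, sub in groups:
        if fmt == "tsv-dosage":
            if "dosage" not in sub.columns:
                raise ValueError(f"locus {lid}: tsv-dosage needs a 'dosage' column")
            dosages = sub["dosage"].to_numpy(dtype=int)
            if dosages.min() < 0 or dosages.max() > ploidy:
                raise ValueError(f"locus {lid}: dosages outside 0..{ploidy}")
            x = np.bincount(dosages, minlength=ploidy + 1)
            data = GenotypeCounts(x)
        else:
            cols = [f"g{k}" for k in range(ploidy + 1)]
            missing = [c for c in cols if c not in sub.columns]
            if missing:
                raise ValueError(f"locus {lid}: missing likelihood columns {missing}")
            g = sub[cols].to_numpy(dtype=float)
            g = np.where(np.isnan(g), 1.0, g)  # missing -> uninformative
            flat = g.sum(axis=1) <= 0
            g[flat] = 1.0
            data = GenotypeLikelihoods.from_linear(g)
        table.loci.append(
            LocusRecord(locus_id=str(lid), data=data, parent_dosages=parent_dosages)
        )
    if "sample" in df.columns:
        table.samples = list(dict.fromkeys(df["sample"].astype(str)))
    return table


def run_tests(table: LocusTable, spec: NullModelSpec, *, families=None,
              **fit_opts) -> pd.DataFrame:
    """Test every locus and attach BH-adjusted q-values.

    ``families`` switches on comparison mode: each listed family is fitted
    per locus and its p-value and BIC reported side by side (columns
    ``p_<family>``/``bic_<family>``); the headline ``p_value``/``q_value``
    then come from ``spec.family``.  Per-locus failures are recorded in the
    ``error`` column and do not abort the run.
    """
    rows = []
    for rec in table.loci:
        row = {"locus": rec.locus_id, "chrom": rec.chrom, "pos": rec.pos}
        l1, l2 = rec.parent_dosages or (spec.l1, spec.l2)
        locus_spec = replace(spec, l1=l1, l2=l2)
        try:
            res = test_locus(rec.data, locus_spec, **fit_opts)
            row.update(
                stat=res.stat, df=res.df, p_value=res.p_value, bic=res.bic,
                pi_hat=res.null_fit.params.pi,
                l1=(res.null_fit.chosen_parents or (l1, l2))[0],
                l2=(res.null_fit.chosen_parents or (l1, l2))[1],
                n_outliers=int((res.outlier_posteriors > 0.5).sum()),
                error="",
            )
            for fam in families or ():
                fres = test_locus(rec.data, replace(locus_spec, family=fam), **fit_opts)
                row[f"p_{fam}"] = fres.p_value
                row[f"bic_{fam}"] = fres.bic
        except Exception as exc:  # keep going; record the failure
            logger.warning("locus %s failed: %s", rec.locus_id, exc)
            row.update(stat=np.nan, df=0, p_value=np.nan, bic=np.nan,
                       pi_hat=np.nan, l1=l1, l2=l2, n_outliers=0, error=str(exc))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    ok = df["p_value"].notna()
    if ok.any():
        df.loc[ok, "q_value"] = multipletests(
            df.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return df


def write_vcf_gl(path, gl_list, ploidy, *, sample_names=None, locus_ids=None,
                 chrom="1") -> None:
    """Write simulated genotype-likelihood matrices as an uncompressed VCF.

    One record per locus, ``GL`` field in log10 (VCF convention,
    dosage-ordered for a biallelic site).
    """
    gl_list = list(gl_list)
    n = gl_list[0].n
    if sample_names is None:
        sample_names = [f"ind{i + 1}" for i in range(n)]
    if locus_ids is None:
        locus_ids = [f"locus{j + 1}" for j in range(len(gl_list))]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##FORMAT=<ID=GL,Number=G,Type=Float,'
            'Description="Genotype likelihoods, log10">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for j, gl in enumerate(gl_list):
            if gl.ploidy != ploidy:
                raise ValueError("ploidy mismatch in GL matrices")
            fields = [chrom, str(j + 1), str(locus_ids[j]), "A", "T", ".", ".",
                      ".", "GL"]
            log10 = gl.log_g / LN10
            for i in range(gl.n):
                vals = ",".join(
                    "-1000" if not np.isfinite(v) else f"{v:.17g}" for v in log10[i]
                )
                fields.append(vals)
            fh.write("\t".join(fields) + "\n")
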