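"""File formats: methylation-read TSV, phased VCF, results BED, model JSON.

The methylation TSV is a flat text dialect for allele-assigned reads, one
read per line with columns

    read_id  chrom  haplotype_id  allele  cpg_index_start  obs_string

where ``allele`` is 1/2 (0 = unassigned), ``cpg_index_start`` is the 1-based
index of the first covered CpG site in the haplotype's site list, and
``obs_string`` is over {0, 1, .} with '.' marking a covered-range site with
no methylation call. Upstream alignment, duplicate removal and allele
tagging are expected to have been done by the usual WGBS tooling; this
module only consumes their outputs.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .haplotypes import AlleleReadSet, PhasedSnpCluster
from .ising import MISSING, CpelModel, ObservedRead

__all__ = [
    "read_methylation_tsv",
    "write_methylation_tsv",
    "read_phased_vcf",
    "write_results_bed",
    "write_model_json",
    "read_model_json",
    "write_null_cdfs",
    "read_null_cdfs",
]

logger = logging.getLogger(__name__)

_TSV_COLUMNS = ("read_id", "chrom", "haplotype_id", "allele", "cpg_index_start", "obs_string")
_OBS_CHAR = {0: "0", 1: "1", MISSING: "."}
_CHAR_OBS = {"0": 0, "1": 1, ".": MISSING}


def read_methylation_tsv(path, n_sites_by_hap=None):
    """Parse allele-assigned methylation reads.

    Parameters
    ----------
    path : file path of the TSV described in the module docstring.
    n_sites_by_hap : optional dict haplotype_id -> CpG count; when absent the
        count is inferred as the largest covered index per haplotype.

    Returns
    -------
    list of :class:`AlleleReadSet` (alleles 1 and 2 only; unassigned reads
    are excluded from allele-specific fitting and counted in the log).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "read_id":  # header
                continue
            if len(fields) != len(_TSV_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            read_id, chrom, hap_id, allele, start, obs = fields
            try:
                allele = int(allele)
                start = int(start)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if allele not in (0, 1, 2):
                raise ValueError(f"{path}:{lineno}: allele must be 0, 1 or 2")
            if start < 1:
                raise ValueError(f"{path}:{lineno}: cpg_index_start is 1-based")
            bad = set(obs) - set(_CHAR_OBS)
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: invalid state symbol(s) {sorted(bad)!r}"
                )
            rows.append((read_id, chrom, hap_id, allele, start, obs))

    if n_sites_by_hap is None:
        n_sites_by_hap = defaultdict(int)
        for _, _, hap_id, _, start, obs in rows:
            n_sites_by_hap[hap_id] = max(
                n_sites_by_hap[hap_id], start - 1 + len(obs)
            )

    sets: dict = {}
    n_unassigned = 0
    for read_id, chrom, hap_id, allele, start, obs in rows:
        if allele == 0:
            n_unassigned += 1
            continue
        n = n_sites_by_hap[hap_id]
        if start - 1 + len(obs) > n:
            raise ValueError(
                f"read {read_id} extends past haplotype {hap_id} "
                f"({start - 1 + len(obs)} > {n} sites)"
            )
        vec = np.full(n, MISSING, dtype=np.int8)
        for i, ch in enumerate(obs):
            vec[start - 1 + i] = _CHAR_OBS[ch]
        key = (hap_id, allele)
        if key not in sets:
            sets[key] = AlleleReadSet(haplotype_id=hap_id, allele=allele)
        sets[key].reads.append(ObservedRead(allele=allele, obs=vec))

    if n_unassigned:
        logger.info("excluded %d unassigned reads", n_unassigned)
    if not sets and rows:
        logger.warning("file contains only unassigned reads")
    return sorted(sets.values(), key=lambda s: (s.haplotype_id, s.allele))


def write_methylation_tsv(readsets, path, chrom_by_hap=None):
    """Write allele read sets in the methylation TSV dialect.

    Reads are trimmed to their covered range (leading/trailing missing
    entries become the ``cpg_index_start`` offset and a shorter string).
    """
    chrom_by_hap = chrom_by_hap or {}
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        counter = 0
        for rs in readsets:
            chrom = chrom_by_hap.get(rs.haplotype_id, ".")
            for read in rs.reads:
                covered = np.flatnonzero(read.obs != MISSING)
                if covered.size == 0:
                    continue
                lo, hi = int(covered[0]), int(covered[-1])
                obs = "".join(_OBS_CHAR[int(v)] for v in read.obs[lo : hi + 1])
                counter += 1
                fh.write(
                    f"read{counter}\t{chrom}\t{rs.haplotype_id}\t{rs.allele}"
                    f"\t{lo + 1}\t{obs}\n"
                )


def read_phased_vcf(path):
    """Extract phased heterozygous SNP clusters from a VCF.

    Heterozygous records with a phased genotype (GT using '|') sharing a
    phase set (PS) on the same chromosome form one cluster. Unphased or
    PS-less genotypes are skipped with a warning. The first sample column
    is used.
    """
    clusters: dict = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: VCF record needs a sample column")
            chrom, pos = fields[0], int(fields[1])
            fmt = fields[8].split(":")
            sample = fields[9].split(":")
            entry = dict(zip(fmt, sample))
            gt = entry.get("GT", "")
            if "|" not in gt:
                n_skipped += 1
                continue
            alleles = gt.split("|")
            if len(alleles) != 2 or alleles[0] == alleles[1]:
                continue  # homozygous or non-diploid
            ps = entry.get("PS")
            if ps is None or ps == ".":
                n_skipped += 1
                continue
            clusters.setdefault((chrom, ps), []).append(pos)
    if n_skipped:
        logger.warning("skipped %d unphased/PS-less genotypes", n_skipped)
    return [
        PhasedSnpCluster(chrom=chrom, positions=tuple(sorted(pos)), phase_set=ps)
        for (chrom, ps), pos in sorted(clusters.items())
    ]


def results_frame(results) -> pd.DataFrame:
    """Tabulate haplotype results (BED-like, 0-based half-open)."""
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "id": r.haplotype_id,
                "N1": r.summary1.n_sites,
                "N2": r.summary2.n_sites,
                "MML1": r.summary1.mml,
                "MML2": r.summary2.mml,
                "NME1": r.summary1.nme,
                "NME2": r.summary2.nme,
                "JSD": r.stats.jsd,
                "T_MML": r.stats.t_mml,
                "T_NME": r.stats.t_nme,
                "T_PDM": r.stats.t_pdm,
                "P_MML": r.p_mml,
                "P_NME": r.p_nme,
                "P_PDM": r.p_pdm,
                "Q_MML": r.q_mml,
                "Q_NME": r.q_nme,
                "Q_PDM": r.q_pdm,
            }
        )
    columns = [
        "chrom", "start", "end", "id", "N1", "N2", "MML1", "MML2", "NME1",
        "NME2", "JSD", "T_MML", "T_NME", "T_PDM", "P_MML", "P_NME", "P_PDM",
        "Q_MML", "Q_NME", "Q_PDM",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_results_bed(results, out_prefix, q_threshold: float = 0.05):
    """Write the master table and the three significant-haplotype lists.

    Produces ``<prefix>.bed`` plus ``<prefix>.mml_haps.bed``,
    ``<prefix>.nme_haps.bed`` and ``<prefix>.pdm_haps.bed`` filtered at
    Q <= ``q_threshold``.
    """
    frame = results_frame(results)
    frame.to_csv(f"{out_prefix}.bed", sep="\t", index=False)
    for name, qcol in (("mml", "Q_MML"), ("nme", "Q_NME"), ("pdm", "Q_PDM")):
        sig = frame[frame[qcol] <= q_threshold]
        sig.to_csv(f"{out_prefix}.{name}_haps.bed", sep="\t", index=False)


def write_model_json(fit_or_model, path, metadata=None):
    """Serialize a fitted Ising model (or fit results) as JSON."""
    if isinstance(fit_or_model, CpelModel):
        payload = fit_or_model.to_dict()
    else:
        payload = fit_or_model.to_dict()
        if getattr(fit_or_model, "fitted_model", None) is not None:
            payload["model"] = fit_or_model.fitted_model.to_dict()
    if metadata:
        payload["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model_json(path) -> CpelModel:
    with open(path) as fh:
        d = json.load(fh)
    return CpelModel.from_dict(d.get("model", d))


def write_null_cdfs(cdfs, path):
    """Serialize empirical null distributions as a long-format TSV.

    One row per null draw: statistic, n_sites, sample (sorted within each
    statistic/N block). Accepts an iterable of NullCdf or a dict of them.
    """
    if isinstance(cdfs, dict):
        cdfs = list(cdfs.values())
    rows = [
        {"statistic": c.statistic, "n_sites": c.n_sites, "sample": s}
        for c in cdfs
        for s in c.samples
    ]
    pd.DataFrame(rows, columns=["statistic", "n_sites", "sample"]).to_csv(
        path, sep="\t", index=False
    )


def read_null_cdfs(path):
    """Inverse of :func:`write_null_cdfs`: dict (statistic, N) -> NullCdf."""
    from .testing import NullCdf

    frame = pd.read_csv(path, sep="\t")
    out = {}
    for (stat, n), group in frame.groupby(["statistic", "n_sites"]):
        out[(stat, int(n))] = NullCdf(stat, int(n), group["sample"].to_numpy())
    return out
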