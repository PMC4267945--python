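"""File formats and preprocessing.

All tables are tab-separated with a header line; base-pair positions are
1-based (VCF convention). The gradient-table text representation
round-trips bit-exactly: floats are written with repr precision and read
back verbatim.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientSet, TrainingPanel

__all__ = [
    "read_gradients",
    "write_gradients",
    "read_locations",
    "write_locations",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_training_panel",
    "read_vector",
    "write_vector",
    "read_vcf_panel",
    "read_vcf_vector",
    "write_truth",
    "read_truth",
    "write_decoding",
    "write_result_record",
    "ld_prune",
    "file_digest",
]

GRADIENT_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "b", "flag"]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_gradients(grad: GradientSet, path) -> None:
    """Write a gradient-coefficient table (full float precision)."""
    with open(path, "w") as fh:
        fh.write("\t".join(GRADIENT_COLUMNS) + "\n")
        for i in range(grad.n_snps):
            fh.write("\t".join([
                str(grad.snp_ids[i]), str(grad.chrom[i]), str(int(grad.pos[i])),
                _fmt(grad.a[i, 0]), _fmt(grad.a[i, 1]), _fmt(grad.b[i]),
                "1" if grad.flagged[i] else "0",
            ]) + "\n")


def read_gradients(path) -> GradientSet:
    """Read a gradient-coefficient table; validates header and positions."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GRADIENT_COLUMNS:
            raise ValueError(f"{path}: unexpected gradient-table header {header}")
        rows = []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(GRADIENT_COLUMNS):
                raise ValueError(f"{path}:{ln}: expected {len(GRADIENT_COLUMNS)} fields, "
                                 f"got {len(parts)}")
            try:
                rows.append((parts[0], parts[1], int(parts[2]), float(parts[3]),
                             float(parts[4]), float(parts[5]), parts[6] == "1"))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed value ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: empty gradient table")
    snp_ids, chrom, pos, a1, a2, b, flag = map(np.array, zip(*rows))
    try:
        return GradientSet(a=np.column_stack([a1.astype(float), a2.astype(float)]),
                           b=b.astype(float), pos=pos.astype(np.int64), chrom=chrom,
                           snp_ids=snp_ids, flagged=flag.astype(bool))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_locations(sample_ids, locations, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlon\tlat\n")
        for sid, (lon, lat) in zip(sample_ids, np.atleast_2d(locations)):
            fh.write(f"{sid}\t{_fmt(lon)}\t{_fmt(lat)}\n")


def read_locations(path):
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns) != ["sample_id", "lon", "lat"]:
        raise ValueError(f"{path}: expected header 'sample_id lon lat'")
    return df["sample_id"].to_numpy(), df[["lon", "lat"]].to_numpy(dtype=float)


def write_genotype_matrix(genotypes, sample_ids, snp_ids, path) -> None:
    """Rows = samples, columns = SNPs, NA for missing."""
    G = np.asarray(genotypes, dtype=float)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(map(str, snp_ids)) + "\n")
        for sid, row in zip(sample_ids, G):
            vals = ["NA" if not np.isfinite(v) else str(int(v)) for v in row]
            fh.write(str(sid) + "\t" + "\t".join(vals) + "\n")


def read_genotype_matrix(path):
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    sample_ids = df["sample_id"].to_numpy()
    snp_ids = np.array(df.columns[1:])
    G = df.iloc[:, 1:].to_numpy(dtype=float)
    return G, sample_ids, snp_ids


def read_training_panel(genotype_path, locations_path, ploidy: int = 2) -> TrainingPanel:
    """Assemble a training panel from a genotype matrix + locations table."""
    G, sample_ids, snp_ids = read_genotype_matrix(genotype_path)
    loc_ids, locations = read_locations(locations_path)
    order = {sid: i for i, sid in enumerate(loc_ids)}
    missing = [sid for sid in sample_ids if sid not in order]
    if missing:
        raise ValueError(f"{locations_path}: no location for sample(s) {missing[:5]}")
    locations = locations[[order[sid] for sid in sample_ids]]
    return TrainingPanel(genotypes=G, locations=locations, sample_ids=sample_ids,
                         snp_ids=snp_ids, ploidy=ploidy)


def write_vector(values, snp_ids, path) -> None:
    """Per-SNP vector file: `snp_id value` (haplotype 0/1 or genotype 0/1/2)."""
    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write("snp_id\tvalue\n")
        for sid, v in zip(snp_ids, vals):
            fh.write(f"{sid}\t{'NA' if not np.isfinite(v) else int(v)}\n")


def read_vector(path, grad: GradientSet = None) -> np.ndarray:
    """Read a per-SNP vector; if a gradient set is given, enforce SNP order."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"snp_id": str})
    if list(df.columns) != ["snp_id", "value"]:
        raise ValueError(f"{path}: expected header 'snp_id value'")
    if grad is not None:
        if len(df) != grad.n_snps or not np.array_equal(df["snp_id"].to_numpy(), grad.snp_ids):
            raise ValueError(f"{path}: SNP order does not match the gradient table")
    return df["value"].to_numpy(dtype=float)


def _vcf_gt_to_dosage(gt_types_row):
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    return {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


def read_vcf_panel(vcf_path, locations_path, ploidy: int = 2) -> TrainingPanel:
    """Training panel from a (single- or multi-sample) VCF, GT field only."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = np.array(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = var.gt_types.astype(float)  # gts012: 0,1,2 dosage; 3 = unknown
        g[g == 3] = np.nan
        rows.append(g)
    G = np.array(rows).T  # samples x SNPs
    loc_ids, locations = read_locations(locations_path)
    order = {sid: i for i, sid in enumerate(loc_ids)}
    locations = locations[[order[sid] for sid in sample_ids]]
    return TrainingPanel(genotypes=G, locations=locations, sample_ids=sample_ids,
                         snp_ids=np.array(snp_ids), ploidy=ploidy)


def read_vcf_vector(vcf_path, grad: GradientSet = None) -> np.ndarray:
    """Single-sample VCF -> 0/1/2 dosage vector (missing -> NaN)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if len(vcf.samples) != 1:
        raise ValueError(f"{vcf_path}: expected exactly one sample")
    vals, ids = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = float(var.gt_types[0])
        vals.append(np.nan if g == 3 else g)
    v = np.array(vals)
    if grad is not None and (len(v) != grad.n_snps
                             or not np.array_equal(np.array(ids), grad.snp_ids)):
        raise ValueError(f"{vcf_path}: SNP order does not match the gradient table")
    return v


def write_truth(truth, grad: GradientSet, prefix) -> None:
    """Truth tables: per-locus path(s) and ancestor locations."""
    prefix = Path(prefix)
    with open(f"{prefix}.truth_path.tsv", "w") as fh:
        cols = ["locus", "chrom", "pos", "true_state"]
        if truth.maternal_path is not None:
            cols.append("true_state_maternal")
        fh.write("\t".join(cols) + "\n")
        for i in range(len(truth.path)):
            row = [str(i), str(grad.chrom[i]), str(int(grad.pos[i])), str(int(truth.path[i]))]
            if truth.maternal_path is not None:
                row.append(str(int(truth.maternal_path[i])))
            fh.write("\t".join(row) + "\n")
    with open(f"{prefix}.truth_ancestors.tsv", "w") as fh:
        fh.write("ancestor_id\tside\tlon\tlat\n")
        for j, (lon, lat) in enumerate(np.atleast_2d(truth.ancestor_locations)):
            fh.write(f"{j}\tpaternal\t{_fmt(lon)}\t{_fmt(lat)}\n")
        if truth.maternal_locations is not None:
            for j, (lon, lat) in enumerate(np.atleast_2d(truth.maternal_locations)):
                fh.write(f"{j}\tmaternal\t{_fmt(lon)}\t{_fmt(lat)}\n")


def read_truth(prefix):
    path_df = pd.read_csv(f"{Path(prefix)}.truth_path.tsv", sep="\t")
    anc_df = pd.read_csv(f"{Path(prefix)}.truth_ancestors.tsv", sep="\t")
    return path_df, anc_df


def write_decoding(grad: GradientSet, states, posteriors, path) -> None:
    """Locus-level output: `snp_id chrom pos state posterior_1..M`."""
    P = np.atleast_2d(np.asarray(posteriors, dtype=float))
    M = P.shape[1]
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tstate\t"
                 + "\t".join(f"posterior_{j + 1}" for j in range(M)) + "\n")
        for i in range(grad.n_snps):
            fh.write(f"{grad.snp_ids[i]}\t{grad.chrom[i]}\t{int(grad.pos[i])}\t"
                     f"{int(states[i])}\t"
                     + "\t".join(f"{P[i, j]:.6g}" for j in range(M)) + "\n")


def file_digest(path) -> str:
    hasher = hashlib.sha256()
    hasher.update(Path(path).read_bytes())
    return hasher.hexdigest()


def write_result_record(path, *, command: str, seed, parameters: dict,
                        inputs: dict = None, results: dict = None) -> None:
    """JSON metadata record: every run is regenerable from this file."""
    from . import __version__

    record = {
        "tool": "geomix",
        "version": __version__,
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "input_digests": {k: file_digest(v) for k, v in (inputs or {}).items()},
        "results": results or {},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def ld_prune(genotypes, r2_threshold: float = 0.2, window_snps: int = 50,
             step_snps: int = 5) -> np.ndarray:
    """Greedy windowed LD pruning; returns the retained SNP indices.

    Within each sliding window, any pair of retained SNPs with squared
    Pearson genotype correlation above the threshold loses its
    later-positioned member. Missing calls are excluded pairwise. The scan
    is deterministic: windows advance by ``step_snps`` and pairs are visited
    in index order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if window_snps < 2:
        raise ValueError("window must span at least 2 SNPs")
    G = np.asarray(genotypes, dtype=float)
    n, L = G.shape
    keep = np.ones(L, dtype=bool)
    if r2_threshold == 1.0:
        # r^2 can only exceed 1 by rounding; retain everything
        return np.arange(L)
    for start in range(0, max(1, L - 1), step_snps):
        stop = min(L, start + window_snps)
        idx = np.flatnonzero(keep[start:stop]) + start
        if idx.size < 2:
            if stop == L:
                break
            continue
        W = G[:, idx]
        mask = np.isfinite(W)
        Wf = np.where(mask, W, 0.0)
        # pairwise-complete correlation via masked cross-products
        nobs = mask.T.astype(float) @ mask
        s1 = Wf.T @ mask
        s2 = (Wf ** 2).T @ mask
        cross = Wf.T @ Wf
        with np.errstate(invalid="ignore", divide="ignore"):
            # mean1[a, b] = mean of SNP a over rows where both a and b observed,
            # so mean1.T gives the partner SNP's mean on the same row set.
            mean1 = s1 / nobs
            cov = cross / nobs - mean1 * mean1.T
            var1 = s2 / nobs - mean1 ** 2
            r2 = cov ** 2 / (var1 * var1.T)
        k = idx.size
        local = np.ones(k, dtype=bool)
        for a in range(k):
            if not local[a]:
                continue
            for bJ in range(a + 1, k):
                if local[bJ] and np.isfinite(r2[a, bJ]) and r2[a, bJ] > r2_threshold:
                    local[bJ] = False
        keep[idx[~local]] = False
        if stop == L:
            break
    return np.flatnonzero(keep)
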