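"""Validated readers and writers for the plain-text table dialect.

Matrices (genotype, local ancestry) are whitespace-separated with one SNP
per line: ``snp_id v1 v2 ... vN``, values in {0, 1, 2} with ``9`` for
missing.  Vectors are two-column ``id value`` files (``NA`` allowed for
phenotypes); the imputation-quality table is ``snp_id rsq_afr rsq_eur``.
Score tables are TSV with a fixed header; all floating output uses six
significant digits for cross-platform reproducibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (MISSING, GenotypeMatrix, GlobalAncestryVector,
                    ImputationQualityTable, LocalAncestryMatrix, PhenotypeVector)


class ParseError(ValueError):
    """Malformed input table, with 1-based row/column coordinates."""


def _tokenize(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if tokens:
                yield lineno, tokens


def read_matrix(path, kind):
    """Read a genotype / local-ancestry / dosage matrix.

    ``kind`` is one of ``"genotype"``, ``"ancestry"`` or ``"dosage"``;
    integer kinds admit only {0, 1, 2, 9}.
    """
    if kind not in ("genotype", "ancestry", "dosage"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    snp_ids, rows = [], []
    width = None
    for lineno, tokens in _tokenize(path):
        snp_ids.append(tokens[0])
        vals = tokens[1:]
        if width is None:
            width = len(vals)
            if width == 0:
                raise ParseError(f"{path}: row {lineno} has no values")
        elif len(vals) != width:
            raise ParseError(
                f"{path}: row {lineno} has {len(vals)} values, expected {width}")
        if kind == "dosage":
            row = np.empty(width)
            for j, tok in enumerate(vals, start=2):
                try:
                    v = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {lineno}, column {j}: non-numeric "
                        f"token {tok!r}") from None
                if tok == str(MISSING):
                    v = np.nan
                elif not 0 <= v <= 2:
                    raise ParseError(
                        f"{path}: row {lineno}, column {j}: dosage {tok!r} "
                        "outside [0, 2]")
                row[j - 2] = v
        else:
            row = np.empty(width, dtype=np.int8)
            for j, tok in enumerate(vals, start=2):
                if tok not in ("0", "1", "2", "9"):
                    raise ParseError(
                        f"{path}: row {lineno}, column {j}: value {tok!r} "
                        "not in {0,1,2,9}")
                row[j - 2] = int(tok)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    values = np.vstack(rows)
    if kind == "genotype":
        return GenotypeMatrix(snp_ids, values)
    if kind == "ancestry":
        return LocalAncestryMatrix(snp_ids, values)
    g = GenotypeMatrix(snp_ids, np.where(np.isnan(values), MISSING,
                                         np.rint(values)).astype(np.int8),
                       dosage=values)
    return g


def write_matrix(matrix, path):
    """Write a matrix back in the same dialect (lossless round trip)."""
    with open(path, "w") as fh:
        for sid, row in zip(matrix.snp_ids, matrix.values):
            fh.write(sid + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_vector(path, kind):
    """Read a theta / phenotype / rsq table.

    θ and r² values must lie in [0, 1]; ``NA`` maps to missing for
    phenotypes only.  A phenotype file whose observed values are all 0/1
    is typed binary, otherwise quantitative.
    """
    if kind not in ("theta", "phenotype", "rsq"):
        raise ValueError(f"unknown vector kind {kind!r}")
    ids, cols = [], []
    want = 3 if kind == "rsq" else 2
    for lineno, tokens in _tokenize(path):
        if len(tokens) != want:
            raise ParseError(
                f"{path}: row {lineno} has {len(tokens)} columns, expected {want}")
        ids.append(tokens[0])
        vals = []
        for j, tok in enumerate(tokens[1:], start=2):
            if tok == "NA":
                if kind != "phenotype":
                    raise ParseError(
                        f"{path}: row {lineno}: NA is only valid for phenotypes")
                vals.append(np.nan)
                continue
            try:
                vals.append(float(tok))
            except ValueError:
                raise ParseError(
                    f"{path}: row {lineno}, column {j}: non-numeric token "
                    f"{tok!r}") from None
        cols.append(vals)
    if not ids:
        raise ParseError(f"{path}: empty vector file")
    arr = np.asarray(cols, dtype=float)
    if kind == "theta":
        if ((arr < 0) | (arr > 1)).any():
            bad = arr[(arr < 0) | (arr > 1)][0]
            raise ParseError(f"{path}: theta value {bad} outside [0, 1]")
        return GlobalAncestryVector(ids, arr[:, 0])
    if kind == "rsq":
        if ((arr < 0) | (arr > 1)).any():
            raise ParseError(f"{path}: r-squared values must lie in [0, 1]")
        return ImputationQualityTable(ids, arr[:, 0], arr[:, 1])
    y = arr[:, 0]
    obs = y[np.isfinite(y)]
    binary = np.isin(obs, (0.0, 1.0)).all() and obs.size > 0
    return PhenotypeVector(ids, y, kind="binary" if binary else "quantitative")


def write_vector(ids, values, path):
    with open(path, "w") as fh:
        for i, v in zip(ids, np.asarray(values, dtype=float)):
            sv = "NA" if not np.isfinite(v) else format(v, ".6g")
            fh.write(f"{i} {sv}\n")


def validate_dataset(geno, anc, theta, pheno, theta_tol=0.1):
    """Consistency report across the four inputs.

    Dimension or id-alignment failures are hard errors; monomorphic SNPs
    and individuals whose mean local ancestry departs from θ by more than
    ``theta_tol`` are structured warnings.
    """
    errors, warnings, monomorphic = [], [], []
    if geno.values.shape != anc.values.shape:
        errors.append(
            f"genotype matrix {geno.values.shape} and ancestry matrix "
            f"{anc.values.shape} have different dimensions")
    if geno.snp_ids != anc.snp_ids:
        errors.append("SNP ids differ between genotype and ancestry matrices")
    n_ind = geno.values.shape[1]
    for name, vec in (("theta", theta.ids), ("phenotype", pheno.ids)):
        if len(vec) != n_ind:
            errors.append(f"{name} has {len(vec)} individuals, matrices have {n_ind}")
    if not errors:
        for i, sid in enumerate(geno.snp_ids):
            row = geno.values[i]
            obs = row[row != MISSING]
            if obs.size and (obs == obs[0]).all():
                monomorphic.append(sid)
                warnings.append(f"SNP {sid} is monomorphic")
        anc_f = np.where(anc.values == MISSING, np.nan, anc.values.astype(float))
        with np.errstate(invalid="ignore"):
            mean_local = np.nanmean(anc_f / 2.0, axis=0)
        off = np.abs(mean_local - theta.theta) > theta_tol
        for j in np.flatnonzero(off & np.isfinite(mean_local)):
            warnings.append(
                f"individual {theta.ids[j]}: mean local ancestry "
                f"{mean_local[j]:.3f} departs from theta {theta.theta[j]:.3f}")
    return {"errors": errors, "warnings": warnings, "monomorphic": monomorphic,
            "ok": not errors}


def write_score_table(table, path):
    """Write a score table as TSV at six significant digits."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: format(v, ".6g"))
    out.to_csv(path, sep="\t", index=False)


def read_score_table(path):
    return pd.read_csv(path, sep="\t")
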