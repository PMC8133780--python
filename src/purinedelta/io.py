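"""Plain-text readers and writers.

Intensity matrices travel as TSV with metabolite rows and sample columns;
an empty cell (or ``NA``) is a missing value.  The scale flag is kept in
a ``# scale=`` comment on the first line so a table round-trips without a
sidecar file.  Sample metadata, pathway maps and simulation truth use
small TSVs with fixed column names.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import IntensityTable, PathwayMap
from .synthetic import SyntheticTruth

_NA = ("", "NA", "NaN", "nan")


def write_intensity_tsv(table: IntensityTable, values_path, meta_path=None) -> None:
    with open(values_path, "w") as fh:
        fh.write(f"# scale={table.scale}\n")
        table.values.to_csv(fh, sep="\t", index_label="metabolite_id", na_rep="")
    if meta_path is not None:
        write_sample_meta_tsv(table.samples, meta_path)


def read_intensity_tsv(values_path, meta_path=None, scale=None) -> IntensityTable:
    with open(values_path) as fh:
        first = fh.readline()
        if first.startswith("# scale="):
            file_scale = first.strip().split("=", 1)[1]
        else:
            file_scale = None
            fh.seek(0)
        values = pd.read_csv(fh, sep="\t", index_col="metabolite_id",
                             na_values=list(_NA), keep_default_na=False)
    scale = scale or file_scale
    if scale is None:
        raise ValueError("scale not recorded in file and not supplied")
    values.columns = values.columns.astype(str)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    if meta_path is not None:
        samples = read_sample_meta_tsv(meta_path)
    else:
        samples = pd.DataFrame({"group": ["unknown"] * values.shape[1]},
                               index=values.columns)
        samples.index.name = "sample_id"
    return IntensityTable(values=values, samples=samples, scale=scale)


def write_sample_meta_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_sample_meta_tsv(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id",
                          na_values=list(_NA), keep_default_na=False)
    samples.index = samples.index.astype(str)
    if "run_order" in samples.columns:
        samples["run_order"] = pd.to_numeric(samples["run_order"], errors="coerce")
    return samples


# -- pathway map -------------------------------------------------------------

def write_pathway_map_tsv(pmap: PathwayMap, path) -> None:
    rows = []
    for metabolite in sorted(pmap.membership):
        for pathway in sorted(pmap.membership[metabolite]):
            rows.append({
                "metabolite_id": metabolite,
                "pathway_id": pathway,
                "pathway_name": pmap.pathway_names.get(pathway, pathway),
                "purine_flag": int(metabolite in pmap.purine_flag),
            })
    pd.DataFrame(rows, columns=["metabolite_id", "pathway_id",
                                "pathway_name", "purine_flag"]
                 ).to_csv(path, sep="\t", index=False)


def read_pathway_map_tsv(path) -> PathwayMap:
    df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str,
                                            "pathway_id": str,
                                            "pathway_name": str})
    membership: dict[str, set] = {}
    names: dict[str, str] = {}
    flag: set = set()
    for row in df.itertuples(index=False):
        membership.setdefault(row.metabolite_id, set()).add(row.pathway_id)
        names[row.pathway_id] = row.pathway_name
        if int(row.purine_flag):
            flag.add(row.metabolite_id)
    return PathwayMap(membership=membership, pathway_names=names, purine_flag=flag)


# -- simulation truth --------------------------------------------------------

def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Long-format truth table: one row per (metabolite, group) mean plus
    marker rows for outlier samples and drift metabolites."""
    rows = []
    for metabolite, group_means in truth.true_group_means.iterrows():
        for group, mean in group_means.items():
            rows.append({"record": "group_mean", "id": metabolite,
                         "key": group, "value": repr(float(mean)),
                         "affected": int(metabolite in truth.affected_metabolites)})
    for s in sorted(truth.outlier_samples):
        rows.append({"record": "outlier_sample", "id": s, "key": "", "value": "",
                     "affected": ""})
    for m in sorted(truth.drift_metabolites):
        rows.append({"record": "drift_metabolite", "id": m, "key": "", "value": "",
                     "affected": ""})
    pd.DataFrame(rows, columns=["record", "id", "key", "value", "affected"]
                 ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=list(_NA),
                     keep_default_na=False)
    gm = df[df["record"] == "group_mean"]
    means = gm.pivot(index="id", columns="key", values="value").astype(float)
    means.index.name = None
    means.columns.name = None
    affected = set(gm.loc[gm["affected"].astype(float) > 0, "id"])
    outliers = set(df.loc[df["record"] == "outlier_sample", "id"])
    drift = set(df.loc[df["record"] == "drift_metabolite", "id"])
    return SyntheticTruth(true_group_means=means, affected_metabolites=affected,
                          outlier_samples=outliers, drift_metabolites=drift)
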