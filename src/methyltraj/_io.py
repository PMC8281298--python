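"""Plain-text readers/writers for the pipeline's artifact formats.

Matrices are probes x samples TSV with the probe id in the first column;
sample sheets are CSV (sample_id, stage, day); annotation is TSV indexed by
probe id; networks are TSV edge lists; ground truth is JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                      na_values=[])
    for col in ("snp_flag", "crossreactive_flag"):
        if col in ann.columns and ann[col].dtype == object:
            ann[col] = ann[col].isin(["True", "true", "1", "TRUE"])
    return ann


def write_network(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_study(study, out_dir) -> None:
    """Write every artifact of a simulated study to a directory."""
    from methyltraj.clocks import write_clock_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(study.beta, out / "beta.tsv")
    write_matrix(study.meth, out / "meth.tsv")
    write_matrix(study.unmeth, out / "unmeth.tsv")
    write_matrix(study.detp, out / "detp.tsv")
    write_matrix(study.beadcount, out / "beadcount.tsv")
    write_samples(study.samples, out / "samples.csv")
    write_annotation(study.annotation, out / "annotation.tsv")
    write_clock_csv(study.clock, out / "clock.csv")
    write_network(study.network_edges, out / "network.tsv")
    study.truth.to_json(out / "truth.json")
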