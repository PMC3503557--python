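"""Readers and writers for the standard input and output formats.

Inputs: a samples x predictors table (TSV/CSV, header row of predictor
names), the response as a named column or a separate single-column file, a
network as SIF (``node  interaction  node``) or headerless 2-column edge
list, and pathways as GMT (set name, description, members).  Outputs:
inclusion probabilities and the EB grid as TSV, the MAP model and run
metadata as JSON.  Predictors are identified by name everywhere; column
order is never semantic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .priors import Network, PathwayAnnotation

__all__ = [
    "RunConfig",
    "read_data_matrix",
    "write_data_matrix",
    "read_network",
    "read_pathways_gmt",
    "write_network_sif",
    "write_pathways_gmt",
    "read_network_and_pathways",
    "write_world",
]

logger = logging.getLogger("ebvs")


@dataclass
class RunConfig:
    """Effective configuration of a selection run (flags > file > defaults)."""

    d_max: int = 4
    interactions: bool = True
    lambda_min: float = -5.0
    lambda_max: float = 5.0
    lambda_step: float = 0.5
    priors: Tuple[str, ...] = ("pathway_count", "intra_pathway_distance")
    seed: int = 0

    def lambda_grid(self) -> np.ndarray:
        from .empirical_bayes import default_lambda_grid

        return default_lambda_grid(self.lambda_min, self.lambda_max, self.lambda_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priors"] = list(self.priors)
        return d


def _sep_for(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_data_matrix(
    path: Union[str, Path],
    response: Optional[str] = None,
    response_path: Optional[Union[str, Path]] = None,
) -> Tuple[np.ndarray, Tuple[str, ...], Optional[np.ndarray]]:
    """Read (X, predictor names, Y) from a delimited table.

    The response is either a named column of the table (removed from X) or a
    separate single-column file.  Non-numeric cells, missing values and
    duplicate names raise SchemaError with row/column context.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate column names {dups}")
    y = None
    if response is not None:
        if response not in df.columns:
            raise SchemaError(f"{path}: no response column named {response!r}")
        ycol = pd.to_numeric(df[response], errors="coerce")
        if ycol.isna().any():
            i = int(ycol.isna().idxmax())
            raise SchemaError(
                f"{path}: non-numeric or missing response at row {i}, "
                f"column {response!r}"
            )
        y = ycol.to_numpy(dtype=float)
        df = df.drop(columns=[response])
    elif response_path is not None:
        ydf = pd.read_csv(response_path, sep=_sep_for(response_path),
                          float_precision="round_trip")
        if ydf.shape[1] != 1:
            raise SchemaError(f"{response_path}: expected a single response column")
        y = pd.to_numeric(ydf.iloc[:, 0], errors="coerce")
        if y.isna().any():
            i = int(y.isna().idxmax())
            raise SchemaError(f"{response_path}: non-numeric response at row {i}")
        y = y.to_numpy(dtype=float)

    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise SchemaError(
                f"{path}: non-numeric or missing value at row {i}, column {col!r}"
            )
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise SchemaError(f"{path}: non-finite values in predictor matrix")
    if y is not None and y.size != X.shape[0]:
        raise SchemaError("response length does not match predictor rows")
    return X, tuple(str(c) for c in df.columns), y


def write_data_matrix(
    path: Union[str, Path],
    X: np.ndarray,
    names: Sequence[str],
    y: Optional[np.ndarray] = None,
    response_name: str = "response",
) -> None:
    df = pd.DataFrame(np.asarray(X), columns=list(names))
    if y is not None:
        df[response_name] = np.asarray(y)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_network(path: Union[str, Path]) -> Network:
    """Read a SIF (node, interaction, node) or 2-column edge list; directed
    edges are symmetrised."""
    edges = []
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                nodes.append(parts[0])
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                # SIF: source, interaction type, one or more targets
                src = parts[0]
                for tgt in parts[2:]:
                    edges.append((src, tgt))
            else:
                raise SchemaError(f"{path}:{lineno}: unparsable network line")
    return Network(edges, nodes=nodes or None)


def write_network_sif(
    path: Union[str, Path], net: Network, interaction: str = "pp"
) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_pathways_gmt(path: Union[str, Path]) -> PathwayAnnotation:
    """GMT: tab-separated set name, description, member names."""
    sets: Dict[str, Tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description, members"
                )
            name = parts[0]
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate pathway {name!r}")
            sets[name] = tuple(m for m in parts[2:] if m)
    return PathwayAnnotation.from_sets(sets)


def write_pathways_gmt(path: Union[str, Path], ann: PathwayAnnotation) -> None:
    with open(path, "w") as fh:
        for name, members in ann.pathways.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_network_and_pathways(
    network_path: Union[str, Path],
    gmt_path: Union[str, Path],
    predictor_names: Sequence[str],
) -> Tuple[Network, PathwayAnnotation]:
    """Load and cross-validate the network and pathway annotation.

    Network nodes absent from the predictors are kept (with a warning);
    pathway members that are neither predictors nor network nodes are
    excluded with a warning.  Disconnected pathway subgraphs are a hard
    error, since intra-pathway distances would be undefined.
    """
    net = read_network(network_path)
    ann = read_pathways_gmt(gmt_path)
    known = set(predictor_names)
    extra = sorted(set(net.nodes) - known)
    if extra:
        logger.warning(
            "network has %d node(s) absent from the predictors: %s",
            len(extra),
            ", ".join(extra[:10]),
        )
    cleaned = {}
    net_nodes = set(net.nodes)
    for name, members in ann.pathways.items():
        keep = frozenset(m for m in members if m in known or m in net_nodes)
        dropped = len(members) - len(keep)
        if dropped:
            logger.warning(
                "pathway %r: excluded %d unknown member(s)", name, dropped
            )
        cleaned[name] = keep
    ann = PathwayAnnotation(cleaned)
    ann.validate(net)
    return net, ann


def write_world(outdir: Union[str, Path], world) -> Dict[str, Path]:
    """Serialise a synthetic world to the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": outdir / "data.tsv",
        "network": outdir / "network.sif",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_data_matrix(paths["data"], world.X, world.names, y=world.Y)
    write_network_sif(paths["network"], world.network)
    write_pathways_gmt(paths["pathways"], world.pathways)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "truth": [world.names[j] for j in world.truth.indices],
                "truth_roles": [world.names[j] for j in world.truth_roles],
                "scenario": world.scenario.scenario,
                "seed": world.seed,
                "noise_sd": world.noise_sd,
            },
            fh,
            indent=2,
        )
    return paths


def write_inclusion_probs(
    path: Union[str, Path], names: Sequence[str], probs: np.ndarray
) -> None:
    pd.DataFrame({"predictor": list(names), "probability": probs}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_run_summary(path: Union[str, Path], summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
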