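"""Reading and writing TraceSets.

Two equivalent on-disk dialects, both round-trip lossless:

* plain delimited text (``.tsv``): a ``#``-prefixed header block with
  the metadata and the JSON-encoded protocol, then a tab-separated
  body whose first column is time (ms) and remaining columns are one
  sweep each (pA), named by the sweep condition;
* HDF5 (``.h5``): datasets ``time``, ``sweep_keys``, ``currents`` plus
  the same metadata as root attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .protocols import VClampProtocol
from .synth import TraceSet

__all__ = ["write_traceset", "read_traceset"]

_MAGIC = "navkit traceset v1"


def _protocol_to_json(p: VClampProtocol) -> str:
    d = dataclasses.asdict(p)
    d["step_voltages"] = list(d["step_voltages"])
    d["recovery_times"] = list(d["recovery_times"])
    return json.dumps(d)


def _protocol_from_json(s: str) -> VClampProtocol:
    d = json.loads(s)
    d["step_voltages"] = tuple(d["step_voltages"])
    d["recovery_times"] = tuple(d["recovery_times"])
    return VClampProtocol(**d)


def _meta(ts: TraceSet) -> dict:
    return {
        "genotype": ts.genotype,
        "temperature": ts.temperature,
        "phenotype_id": ts.phenotype_id,
        "capacitance": ts.capacitance,
        "noise_sd": ts.noise_sd,
        "seed": -1 if ts.seed is None else int(ts.seed),
    }


def write_traceset(ts: TraceSet, path) -> Path:
    """Write a TraceSet; the dialect is chosen by extension
    (``.h5``/``.hdf5`` -> HDF5, anything else -> delimited text)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["magic"] = _MAGIC
            f.attrs["protocol"] = _protocol_to_json(ts.protocol)
            for k, v in _meta(ts).items():
                f.attrs[k] = v
            f.create_dataset("time", data=ts.time)
            f.create_dataset("sweep_keys", data=ts.sweep_keys)
            f.create_dataset("currents", data=ts.currents)
        return path

    lines = [f"# {_MAGIC}"]
    lines.append(f"# protocol\t{_protocol_to_json(ts.protocol)}")
    for k, v in _meta(ts).items():
        lines.append(f"# {k}\t{json.dumps(v)}")
    cols = "\t".join(["time_ms"] + [f"sweep_{k:g}" for k in ts.sweep_keys])
    lines.append(cols)
    body = np.column_stack([ts.time, ts.currents.T])
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
        np.savetxt(f, body, fmt="%.17g", delimiter="\t")
    return path


def read_traceset(path) -> TraceSet:
    """Read a TraceSet written by :func:`write_traceset`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if f.attrs.get("magic") != _MAGIC:
                raise ValueError(f"{path} is not a navkit traceset")
            meta = {k: f.attrs[k] for k in
                    ("genotype", "temperature", "phenotype_id",
                     "capacitance", "noise_sd", "seed")}
            protocol = _protocol_from_json(f.attrs["protocol"])
            time = f["time"][:]
            keys = f["sweep_keys"][:]
            currents = f["currents"][:]
        seed = int(meta["seed"])
        return TraceSet(
            time=time, sweep_keys=keys, currents=currents,
            capacitance=float(meta["capacitance"]), protocol=protocol,
            genotype=str(meta["genotype"]), temperature=float(meta["temperature"]),
            phenotype_id=str(meta["phenotype_id"]),
            noise_sd=float(meta["noise_sd"]), seed=None if seed < 0 else seed,
        )

    meta = {}
    protocol = None
    n_header = 0
    with open(path) as f:
        first = f.readline().rstrip("\n")
        if first != f"# {_MAGIC}":
            raise ValueError(f"{path} is not a navkit traceset")
        n_header = 1
        for line in f:
            n_header += 1
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                if key == "protocol":
                    protocol = _protocol_from_json(val)
                else:
                    meta[key] = json.loads(val)
            else:
                break  # column-name row
    if protocol is None:
        raise ValueError(f"{path}: missing protocol header")
    body = np.loadtxt(path, skiprows=n_header, delimiter="\t", ndmin=2)
    time = body[:, 0]
    currents = body[:, 1:].T
    seed = int(meta["seed"])
    return TraceSet(
        time=time, sweep_keys=np.asarray(protocol.sweep_keys, dtype=float),
        currents=currents, capacitance=float(meta["capacitance"]),
        protocol=protocol, genotype=str(meta["genotype"]),
        temperature=float(meta["temperature"]),
        phenotype_id=str(meta["phenotype_id"]),
        noise_sd=float(meta["noise_sd"]), seed=None if seed < 0 else seed,
    )
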