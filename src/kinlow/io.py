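"""File formats: panel (.snp dialect), frequency/pileup/call/GL TSVs.

All tabular formats are TSV with a header row, floats at 6 significant
digits, gzip-transparent on read and write (paths ending in ``.gz``).
The panel uses a whitespace-separated 6-column EIGENSTRAT-style .snp
dialect: site_id, chrom, genetic position (written as 0.0, ignored on
read), physical position, ref, alt; allele frequencies travel in a
separate two-column TSV.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import platform
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError
from .genotyping import MISSING, GLMatrix, PseudohaploidMatrix
from .panel import SitePanel
from .simulate import ReadPileup

__all__ = [
    "read_panel",
    "write_panel",
    "read_freqs",
    "write_freqs",
    "read_pileup",
    "write_pileup",
    "read_calls",
    "write_calls",
    "read_gls",
    "write_gls",
    "read_gls_vcf",
    "write_results",
    "write_manifest",
]

_VALID_NUC = set("ACGT")


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_panel(panel: SitePanel, snp_path, freq_path=None) -> None:
    """Write the .snp dialect, and the frequency TSV when a path is given."""
    with _open(snp_path, "wt") as fh:
        for sid, c, pos, ref, alt in zip(
            panel.site_id, panel.chrom, panel.pos, panel.ref, panel.alt
        ):
            fh.write(f"{sid}\t{c}\t0.0\t{pos}\t{ref}\t{alt}\n")
    if freq_path is not None:
        write_freqs(panel, freq_path)


def write_freqs(panel: SitePanel, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("site_id\talt_freq\n")
        for sid, f in zip(panel.site_id, panel.alt_freq):
            fh.write(f"{sid}\t{f:.6g}\n")


def read_freqs(path) -> dict[str, float]:
    freqs: dict[str, float] = {}
    with _open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["site_id", "alt_freq"]:
            raise ParseError("frequency file must have columns site_id, alt_freq", line=1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2:
                raise ParseError("expected 2 columns", line=lineno)
            freqs[fields[0]] = float(fields[1])
    return freqs


def read_panel(snp_path, freq_path=None) -> SitePanel:
    """Read the .snp dialect; frequencies from ``freq_path`` or 0.5 stubs.

    The genetic-position column is ignored.  Duplicate ids, non-monotone
    positions and bad allele characters raise a ParseError naming the
    line.
    """
    site_id, chrom, pos, ref, alt = [], [], [], [], []
    seen: dict[str, int] = {}
    last: dict[int, int] = {}
    with _open(snp_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise ParseError(f"expected 6 columns, got {len(fields)}", line=lineno)
            sid, c, _gpos, p, r, a = fields
            if sid in seen:
                raise ParseError(f"duplicate site_id {sid!r} (first at line {seen[sid]})",
                                 line=lineno)
            seen[sid] = lineno
            try:
                c_i, p_i = int(c), int(p)
            except ValueError:
                raise ParseError("chrom and pos must be integers", line=lineno) from None
            if r not in _VALID_NUC or a not in _VALID_NUC:
                raise ParseError(f"bad allele characters {r!r}/{a!r}", line=lineno)
            if c_i in last and p_i <= last[c_i]:
                raise ParseError(
                    f"position {p_i} not increasing on chromosome {c_i}", line=lineno
                )
            last[c_i] = p_i
            site_id.append(sid)
            chrom.append(c_i)
            pos.append(p_i)
            ref.append(r)
            alt.append(a)
    if not site_id:
        raise ParseError("panel file is empty")
    if freq_path is not None:
        fmap = read_freqs(freq_path)
        missing = [s for s in site_id if s not in fmap]
        if missing:
            raise InputError(f"frequency file lacks {len(missing)} panel sites "
                             f"(first: {missing[0]!r})")
        freqs = np.array([fmap[s] for s in site_id])
    else:
        freqs = np.full(len(site_id), 0.5)
    return SitePanel(
        site_id=np.array(site_id), chrom=np.array(chrom), pos=np.array(pos),
        ref=np.array(ref), alt=np.array(alt), alt_freq=freqs,
    )


def write_pileup(pileup: ReadPileup, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("individual_id\tsite_id\tn_ref\tn_alt\n")
        for i, ind in enumerate(pileup.individuals):
            for sid, nr, na in zip(pileup.panel.site_id, pileup.n_ref[i], pileup.n_alt[i]):
                fh.write(f"{ind}\t{sid}\t{nr}\t{na}\n")


def read_pileup(path, panel: SitePanel) -> ReadPileup:
    """Read a pileup TSV, validating ids against the panel."""
    df = pd.read_csv(path, sep="\t")
    expected = ["individual_id", "site_id", "n_ref", "n_alt"]
    for col in expected:
        if col not in df.columns:
            raise ParseError(f"pileup file lacks column {col!r}")
    if (df["n_ref"] < 0).any() or (df["n_alt"] < 0).any():
        raise InputError("read counts must be non-negative")
    site_index = {s: i for i, s in enumerate(panel.site_id)}
    unknown = set(df["site_id"]) - set(site_index)
    if unknown:
        raise InputError(f"pileup references sites absent from panel (e.g. {next(iter(unknown))!r})")
    individuals = list(dict.fromkeys(df["individual_id"]))
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    n_ref = np.zeros((len(individuals), panel.n_sites), dtype=np.int32)
    n_alt = np.zeros_like(n_ref)
    rows = df["individual_id"].map(ind_index).to_numpy()
    cols = df["site_id"].map(site_index).to_numpy()
    n_ref[rows, cols] = df["n_ref"].to_numpy()
    n_alt[rows, cols] = df["n_alt"].to_numpy()
    return ReadPileup(individuals, n_ref, n_alt, panel)


def write_calls(ph: PseudohaploidMatrix, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("individual_id\tsite_id\tcall\n")
        for i, ind in enumerate(ph.individuals):
            for sid, call in zip(ph.panel.site_id, ph.calls[i]):
                fh.write(f"{ind}\t{sid}\t{call}\n")


def read_calls(path, panel: SitePanel) -> PseudohaploidMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "site_id", "call"):
        if col not in df.columns:
            raise ParseError(f"calls file lacks column {col!r}")
    if not df["call"].isin([0, 1, MISSING]).all():
        raise InputError("calls must be 0, 1 or 9")
    site_index = {s: i for i, s in enumerate(panel.site_id)}
    unknown = set(df["site_id"]) - set(site_index)
    if unknown:
        raise InputError(f"calls reference sites absent from panel (e.g. {next(iter(unknown))!r})")
    individuals = list(dict.fromkeys(df["individual_id"]))
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    calls = np.full((len(individuals), panel.n_sites), MISSING, dtype=np.int8)
    rows = df["individual_id"].map(ind_index).to_numpy()
    cols = df["site_id"].map(site_index).to_numpy()
    calls[rows, cols] = df["call"].to_numpy()
    return PseudohaploidMatrix(individuals, calls, panel)


def write_gls(gl: GLMatrix, path) -> None:
    """Write non-missing likelihood triples; missing sites are omitted."""
    with _open(path, "wt") as fh:
        fh.write("individual_id\tsite_id\tl0\tl1\tl2\n")
        for i, ind in enumerate(gl.individuals):
            cov = ~gl.missing[i]
            for sid, (l0, l1, l2) in zip(gl.panel.site_id[cov], gl.likelihoods[i][cov]):
                fh.write(f"{ind}\t{sid}\t{l0:.6g}\t{l1:.6g}\t{l2:.6g}\n")


def read_gls(path, panel: SitePanel, tol: float = 1e-4) -> GLMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "site_id", "l0", "l1", "l2"):
        if col not in df.columns:
            raise ParseError(f"GL file lacks column {col!r}")
    trip = df[["l0", "l1", "l2"]].to_numpy(dtype=float)
    if np.any(trip < 0):
        raise InputError("likelihoods must be non-negative")
    sums = trip.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InputError(f"likelihood triple does not sum to 1 (row {bad + 2})")
    trip = trip / sums[:, None]
    site_index = {s: i for i, s in enumerate(panel.site_id)}
    unknown = set(df["site_id"]) - set(site_index)
    if unknown:
        raise InputError(f"GL file references sites absent from panel (e.g. {next(iter(unknown))!r})")
    individuals = list(dict.fromkeys(df["individual_id"]))
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    lik = np.full((len(individuals), panel.n_sites, 3), np.nan)
    missing = np.ones((len(individuals), panel.n_sites), dtype=bool)
    rows = df["individual_id"].map(ind_index).to_numpy()
    cols = df["site_id"].map(site_index).to_numpy()
    lik[rows, cols] = trip
    missing[rows, cols] = False
    return GLMatrix(individuals, lik, missing, panel)


def read_gls_vcf(path, panel: SitePanel) -> GLMatrix:
    """Adapter: genotype likelihoods from the PL field of a VCF.

    Sites are matched to the panel by (chrom, pos); phred-scaled PL
    triples are converted to normalized linear likelihoods.  Intended as
    an import convenience; bit-exactness with any upstream caller is not
    claimed.
    """
    import pysam  # deferred: optional adapter

    site_index = {(int(c), int(p)): i for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))}
    with pysam.VariantFile(str(path)) as vcf:
        individuals = list(vcf.header.samples)
        lik = np.full((len(individuals), panel.n_sites, 3), np.nan)
        missing = np.ones((len(individuals), panel.n_sites), dtype=bool)
        for rec in vcf:
            try:
                col = site_index[(int(rec.chrom), rec.pos)]
            except (KeyError, ValueError):
                continue
            for i, ind in enumerate(individuals):
                pl = rec.samples[ind].get("PL")
                if pl is None or len(pl) < 3 or any(v is None for v in pl[:3]):
                    continue
                lin = 10.0 ** (-0.1 * np.array(pl[:3], dtype=float))
                lik[i, col] = lin / lin.sum()
                missing[i, col] = False
    return GLMatrix(individuals, lik, missing, panel)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV, floats at 6 significant digits."""
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int, files,
                   name: str = "manifest.json") -> Path:
    """Record a run: config echo, seed, versions, file digests, timestamp."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "kinlow": _package_version(),
        },
        "files": {str(Path(f).name): _digest(f) for f in files},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "argv": sys.argv,
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _package_version() -> str:
    from . import __version__

    return __version__
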