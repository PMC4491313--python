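"""Text-first file formats, configuration, and the pipeline driver.

Reflection data live in plain-text tables with a commented header
(cell, symmetry, resolution range, named columns); per-pattern
observations in a stream-like block format; images in HDF5; maps in
CCP4 format.  ``run_pipeline`` chains simulate -> (render+hitfind) ->
merge -> stats -> validation -> density from a single seeded config and
writes every intermediate plus a run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crystal import StructureFactorSet, UnitCell, default_toy_structure, \
    calc_structure_factors, ToyStructure
from .merge import MergedSet, monte_carlo_merge, MERGED_COLUMNS
from .symmetry import SpaceGroupSetting
from .simulate import (SimulationParams, StillPattern, simulate_stills,
                       render_pattern_image, DetectorGeometry, mark_indexable)

__all__ = [
    "write_reflection_table", "read_reflection_table",
    "write_stream", "read_stream",
    "write_images_hdf5", "read_images_hdf5",
    "PipelineConfig", "RunManifest", "run_pipeline",
]


class ReflectionTableError(ValueError):
    pass


# -- reflection tables -------------------------------------------------

def _header_lines(cell, sg, d_max, d_min, kind, friedel_separate, extra=None):
    lines = [
        "# format: sfxkit-reflections 1",
        f"# kind: {kind}",
        f"# cell: {cell.a:.6g} {cell.b:.6g} {cell.c:.6g} "
        f"{cell.alpha:.6g} {cell.beta:.6g} {cell.gamma:.6g}",
        f"# spacegroup: {sg.symbol}",
        f"# resolution: {d_max:.6g} {d_min:.6g}",
        f"# friedel: {'separate' if friedel_separate else 'merged'}",
    ]
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return lines


def write_reflection_table(obj, path) -> None:
    """Write a MergedSet or StructureFactorSet as a plain-text table."""
    path = Path(path)
    if isinstance(obj, MergedSet):
        header = _header_lines(obj.cell, obj.spacegroup, obj.d_max, obj.d_min,
                               "merged", obj.friedel_separate,
                               {k: v for k, v in obj.provenance.items()
                                if isinstance(v, (int, float, str))})
        df = obj.df.copy()
        df["free"] = df["free"].astype(int)
        cols = list(df.columns)
    elif isinstance(obj, StructureFactorSet):
        header = _header_lines(obj.cell, obj.spacegroup, obj.d_max, obj.d_min,
                               "structure_factors", obj.friedel_separate)
        df = pd.DataFrame({
            "h": obj.hkl[:, 0], "k": obj.hkl[:, 1], "l": obj.hkl[:, 2],
            "amplitude": obj.amplitudes, "phase_deg": obj.phases_deg,
        })
        cols = list(df.columns)
    else:
        raise TypeError("expected MergedSet or StructureFactorSet")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("# columns: " + " ".join(cols) + "\n")
        df.to_csv(fh, sep=" ", header=False, index=False,
                  float_format="%.6g", na_rep="nan")


def _parse_header(path):
    meta, columns, n_header = {}, None, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, val = body.split(":", 1)
            key, val = key.strip(), val.strip()
            if key == "columns":
                columns = val.split()
            else:
                meta[key] = val
    for req in ("cell", "spacegroup", "resolution"):
        if req not in meta:
            raise ReflectionTableError(f"missing header field '{req}' in {path}")
    if columns is None:
        raise ReflectionTableError(f"missing header field 'columns' in {path}")
    return meta, columns, n_header


def read_reflection_table(path):
    """Read a table written by :func:`write_reflection_table`.

    Columns are matched by name (any order); unknown columns are kept.
    Returns a MergedSet or a StructureFactorSet depending on the header.
    """
    path = Path(path)
    meta, columns, n_header = _parse_header(path)
    cell = UnitCell(*(float(x) for x in meta["cell"].split()))
    sg = SpaceGroupSetting.from_symbol(meta["spacegroup"])
    d_max, d_min = (float(x) for x in meta["resolution"].split())
    friedel_separate = meta.get("friedel", "merged") == "separate"
    try:
        df = pd.read_csv(path, sep=r"\s+", skiprows=n_header, header=None,
                         names=columns, comment="#")
    except pd.errors.ParserError as exc:
        raise ReflectionTableError(f"malformed row in {path}: {exc}") from exc
    bad = df[["h", "k", "l"]].isna().any(axis=1)
    if bad.any():
        line_no = int(np.nonzero(bad.to_numpy())[0][0]) + n_header + 1
        raise ReflectionTableError(f"malformed row at line {line_no} of {path}")
    df[["h", "k", "l"]] = df[["h", "k", "l"]].astype(np.int64)

    kind = meta.get("kind", "merged" if "I" in columns else "structure_factors")
    if kind == "structure_factors":
        f = df["amplitude"].to_numpy() * np.exp(1j * np.radians(df["phase_deg"].to_numpy()))
        return StructureFactorSet(cell, sg, d_max, d_min,
                                  df[["h", "k", "l"]].to_numpy(), f,
                                  friedel_separate=friedel_separate)
    missing = [c for c in MERGED_COLUMNS if c not in df.columns]
    if missing:
        raise ReflectionTableError(f"merged table {path} missing columns {missing}")
    df["free"] = df["free"].astype(bool)
    for c in ("n", "n_A", "n_B"):
        df[c] = df[c].astype(int)
    extra = [c for c in df.columns if c not in MERGED_COLUMNS]
    prov = {k: v for k, v in meta.items()
            if k not in ("cell", "spacegroup", "resolution", "friedel",
                         "format", "kind")}
    return MergedSet(cell, sg, d_max, d_min, df[MERGED_COLUMNS + extra],
                     friedel_separate=friedel_separate, provenance=prov)


# -- stream-like pattern files ----------------------------------------

def write_stream(patterns, path) -> None:
    """One text block per pattern: BEGIN PATTERN id / scale / h k l I sigma."""
    with open(path, "w") as fh:
        fh.write("# format: sfxkit-stream 1\n")
        for p in patterns:
            fh.write(f"BEGIN PATTERN {p.pattern_id}\n")
            fh.write(f"scale {p.scale:.6g}\n")
            fh.write("orientation " +
                     " ".join(f"{x:.8g}" for x in p.orientation.ravel()) + "\n")
            for h, i, s in zip(p.hkl.tolist(), p.intensity, p.sigma):
                fh.write(f"{h[0]} {h[1]} {h[2]} {i:.6g} {s:.6g}\n")
            fh.write("END PATTERN\n")


def read_stream(path) -> list:
    patterns = []
    pid = scale = orient = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or line.startswith("#"):
                continue
            if tok[0] == "BEGIN":
                pid, scale, orient, rows = int(tok[2]), 1.0, np.eye(3), []
            elif tok[0] == "scale":
                scale = float(tok[1])
            elif tok[0] == "orientation":
                orient = np.array([float(x) for x in tok[1:]]).reshape(3, 3)
            elif tok[0] == "END":
                arr = np.array(rows, dtype=float) if rows else np.empty((0, 5))
                patterns.append(StillPattern(
                    pattern_id=pid, orientation=orient, scale=scale,
                    hkl=arr[:, :3].astype(np.int64),
                    intensity=arr[:, 3], sigma=arr[:, 4]))
            else:
                if len(tok) != 5:
                    raise ValueError(f"malformed stream row at line {ln}")
                rows.append([float(x) for x in tok])
    return patterns


def write_images_hdf5(images, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for im in images:
            ds = fh.create_dataset(f"pattern_{im.pattern_id:06d}", data=im.pixels)
            ds.attrs["pixel_um"] = im.geometry.pixel_um
            ds.attrs["distance_mm"] = im.geometry.distance_mm
            ds.attrs["wavelength"] = im.geometry.wavelength


def read_images_hdf5(path):
    import h5py
    from .simulate import DetectorImage

    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            ds = fh[name]
            geom = DetectorGeometry(
                n_rows=ds.shape[0], n_cols=ds.shape[1],
                pixel_um=float(ds.attrs.get("pixel_um", 110.0)),
                distance_mm=float(ds.attrs.get("distance_mm", 130.0)),
                wavelength=float(ds.attrs.get("wavelength", 2.07)),
            )
            out.append(DetectorImage(ds[()], geom,
                                     int(name.rsplit("_", 1)[1])))
    return out


# -- pipeline ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat, fully explicit run configuration; round-trips through YAML."""

    seed: int = 1
    structure_pdb: str | None = None   # None -> builtin toy structure
    d_max: float = 30.0
    d_min: float = 2.5
    n_patterns: int = 500
    scale_sigma: float = 0.3
    sigma_m: float = 1.0
    noise_floor_frac: float = 0.05
    noise_poisson_b: float = 1.0
    excite_rate: float = 0.05
    anomalous: bool = False
    render_images: bool = False
    n_images: int = 20
    image_background: float = 50.0
    image_gain: float = 30.0
    free_fraction: float = 0.05
    n_shells: int = 10
    run_validation: bool = False
    splice_cutoffs: tuple = ()
    resolve_ladder: tuple = ()
    run_density: bool = False
    omit_atom_index: int | None = None
    map_sigma_level: float = 3.0
    out_dir: str = "sfxkit_run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["splice_cutoffs"] = list(self.splice_cutoffs)
        d["resolve_ladder"] = list(self.resolve_ladder)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("splice_cutoffs", "resolve_ladder"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = self.as_dict()
        payload.pop("out_dir")  # where outputs go is not what is computed
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: list = field(default_factory=list)  # (name, seconds, outputs)

    def add(self, name, seconds, outputs):
        self.stages.append({"stage": name, "seconds": round(seconds, 3),
                            "outputs": [str(o) for o in outputs]})

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages},
                      fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages, writing every intermediate under
    ``config.out_dir``; any stage error aborts but completed outputs stay."""
    from . import hitfinder, metrics, validate, density

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config.config_hash())

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.outputs = []
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.add(name, time.perf_counter() - self.t0, self.outputs)
                manifest.write(out / "manifest.json")
                return False
        return _Timer()

    if config.structure_pdb:
        structure = ToyStructure.from_pdb(config.structure_pdb)
    else:
        structure = default_toy_structure()
    with stage("structure_factors") as st:
        structure.to_pdb(out / "structure.pdb")
        sfs = calc_structure_factors(structure, config.d_max, config.d_min,
                                     anomalous=config.anomalous)
        write_reflection_table(sfs, out / "model_sf.txt")
        st.outputs += [out / "structure.pdb", out / "model_sf.txt"]

    params = SimulationParams(
        n_patterns=config.n_patterns, scale_sigma=config.scale_sigma,
        sigma_m=config.sigma_m, noise_floor_frac=config.noise_floor_frac,
        noise_poisson_b=config.noise_poisson_b, excite_rate=config.excite_rate,
        seed=config.seed, anomalous=config.anomalous,
    )
    with stage("simulate") as st:
        patterns = simulate_stills(sfs, params)
        write_stream(patterns, out / "patterns.stream")
        st.outputs.append(out / "patterns.stream")

    if config.render_images:
        with stage("hitfind") as st:
            images = [render_pattern_image(
                p, sfs, background_level=config.image_background,
                gain=config.image_gain) for p in patterns[: config.n_images]]
            write_images_hdf5(images, out / "images.h5")
            n_hits = 0
            with open(out / "peaks.tsv", "w") as fh:
                fh.write("pattern\trow\tcol\tadu\tsnr\n")
                for im in images:
                    pl = hitfinder.find_peaks(im)
                    n_hits += hitfinder.classify_hit(pl)
                    for p in pl.peaks:
                        fh.write(f"{pl.pattern_id}\t{p.row:.1f}\t{p.col:.1f}"
                                 f"\t{p.integrated_adu:.1f}\t{p.snr:.1f}\n")
            indexed = int(np.sum(mark_indexable(patterns[: config.n_images])
                                 & np.array([True] * len(images))))
            tally = hitfinder.tally_rates(len(images), n_hits,
                                          min(indexed, n_hits))
            (out / "tally.tsv").write_text(
                "frames\thits\thit_pct\tindexed\tindexed_pct\n"
                f"{tally.frames}\t{tally.hits}\t{tally.hit_percent}\t"
                f"{tally.indexed}\t{tally.indexed_percent}\n")
            st.outputs += [out / "images.h5", out / "peaks.tsv", out / "tally.tsv"]

    with stage("merge") as st:
        merged = monte_carlo_merge(
            patterns, structure.cell, structure.spacegroup,
            config.d_max, config.d_min,
            friedel_merge=not config.anomalous, split_seed=config.seed,
            free_fraction=config.free_fraction)
        write_reflection_table(merged, out / "merged.txt")
        st.outputs.append(out / "merged.txt")

    with stage("stats") as st:
        table = metrics.summarize_shells(merged, n_shells=config.n_shells,
                                         structure=structure)
        (out / "shells.tsv").write_text(
            table.shells.to_csv(sep="\t", index=False) +
            "# overall: " + json.dumps(table.overall, default=float) + "\n")
        st.outputs.append(out / "shells.tsv")

    if config.run_validation and config.splice_cutoffs:
        with stage("scramble_chimera") as st:
            spec = validate.ScrambleSpec(seed=config.seed,
                                         cutoffs=tuple(config.splice_cutoffs))
            scrambled = validate.scramble_intensities(merged, spec)
            write_reflection_table(scrambled, out / "scrambled.txt")
            st.outputs.append(out / "scrambled.txt")
            for cut in spec.cutoffs:
                chim = validate.make_chimeric(merged, scrambled, cut)
                fn = out / f"chimera_{cut:.1f}.txt"
                write_reflection_table(chim, fn)
                st.outputs.append(fn)
    if config.run_validation and config.resolve_ladder:
        with stage("resolve") as st:
            scan = validate.paired_resolution_scan(sfs, merged,
                                                   config.resolve_ladder)
            (out / "resolution_scan.tsv").write_text(
                scan.rungs.to_csv(sep="\t", index=False) +
                f"# effective_resolution: {scan.effective_resolution}\n")
            st.outputs.append(out / "resolution_scan.tsv")

    if config.run_density and config.omit_atom_index is not None:
        with stage("density") as st:
            omit = dataclasses.replace(structure)
            omit.atoms = [a for i, a in enumerate(structure.atoms)
                          if i != config.omit_atom_index]
            omit_sf = calc_structure_factors(omit, config.d_max, config.d_min)
            grid = density.difference_map(merged, omit_sf)
            grid.write_ccp4(out / "difference.ccp4")
            peaks = density.find_map_peaks(grid, config.map_sigma_level)
            with open(out / "map_peaks.tsv", "w") as fh:
                fh.write("x\ty\tz\theight_sigma\tsign\n")
                for p in peaks:
                    fh.write(f"{p.frac[0]:.4f}\t{p.frac[1]:.4f}\t{p.frac[2]:.4f}"
                             f"\t{p.height_sigma:.2f}\t{p.sign:+d}\n")
            st.outputs += [out / "difference.ccp4", out / "map_peaks.tsv"]

    manifest.write(out / "manifest.json")
    return manifest
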