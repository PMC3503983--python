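"""File-level pipeline stages and the reproducible end-to-end runner.

Every stage reads and writes plain-text formats (FASTA, GFF3, TSV) so the
pipeline can be driven from the shell; the run manifest records the package
version, the seed, every resolved parameter and the SHA-256 of every output,
so a rerun with the same config is byte-identical and verifiable.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__, io
from .annotate import (AnnotatedElement, RepeatLibrary, SubFeature, TSD,
                       annotate_region)
from .fates import (FateCategory, NotClassifiableError, classify_element,
                    fate_count_table, mechanism_of)
from .dating import DEFAULT_RATE, date_element
from .movement import (GeneAnnotation, TEAnnotationLite, find_tandem_arrays,
                       flag_retrocopy, scan_helitron_capture, scan_tandem_flank,
                       scan_tsd_capture)
from .sim import FateCategory as _FC  # noqa: F401  (re-export convenience)
from .summary import (TEAnnotation, composition_table, region_profile,
                      chromatin_indicator)


# ---------------------------------------------------------------------------
# GFF3 <-> AnnotatedElement round trip
# ---------------------------------------------------------------------------

def _parse_span(text: str) -> tuple[int, int]:
    s, e = text.split("-")
    return int(s), int(e)


def elements_from_gff3(path) -> list[AnnotatedElement]:
    """Rebuild annotated elements from an elements GFF3 written by this
    package (coordinates converted back to 0-based half-open)."""
    features = io.read_gff3(path)
    elements: dict[str, AnnotatedElement] = {}
    for f in features:
        if f.featuretype != "repeat_region":
            continue
        attrs = {k: v[0] for k, v in f.attributes.items()}
        tsd = None
        if attrs.get("tsd") and attrs.get("tsd_left"):
            tsd = TSD(left_copy=_parse_span(attrs["tsd_left"]),
                      right_copy=_parse_span(attrs["tsd_right"]),
                      sequence=attrs["tsd"])
        elements[attrs["ID"]] = AnnotatedElement(
            element_id=attrs["ID"], family_name=attrs.get("family", "unknown"),
            class_label=attrs.get("class", "Unclassified"), sub_features=[],
            tsd=tsd, strand=f.strand if f.strand in "+-" else "+",
            structural_pair=attrs.get("structural_pair") == "1")
    for f in features:
        if f.featuretype != "repeat_fragment":
            continue
        attrs = {k: v[0] for k, v in f.attributes.items()}
        parent = elements[attrs["Parent"]]
        parent.sub_features.append(SubFeature(
            role=attrs["role"], interval=(f.start - 1, f.end),
            family=attrs.get("family"),
            identity=float(attrs["identity"]) if "identity" in attrs else None,
            coverage=float(attrs["coverage"]) if "coverage" in attrs else None))
    out = list(elements.values())
    for el in out:
        el.sub_features.sort(key=lambda sf: sf.interval)
        el.families_present = frozenset(
            sf.family for sf in el.sub_features if sf.family)
    out.sort(key=lambda el: el.interval)
    return out


def genes_from_gff3(path) -> list[GeneAnnotation]:
    """Genes (with exon sub-intervals when present) from a GFF3 file."""
    features = io.read_gff3(path)
    genes: dict[str, dict] = {}
    for f in features:
        if f.featuretype == "gene":
            gid = f.attributes["ID"][0]
            genes[gid] = {"interval": (f.start - 1, f.end), "exons": []}
    for f in features:
        parents = f.attributes.get("Parent", [])
        role = f.attributes.get("role", [""])[0]
        is_exon = f.featuretype == "exon" or role.startswith("exon")
        if is_exon and parents and parents[0] in genes:
            genes[parents[0]]["exons"].append((f.start - 1, f.end))
    return [GeneAnnotation(gene_id=gid, interval=d["interval"],
                           exons=tuple(sorted(d["exons"])))
            for gid, d in sorted(genes.items())]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_annotate(fasta, library_fa, out_gff3, **params) -> int:
    """annotate: FASTA + library -> elements GFF3; returns element count."""
    sequences = io.read_fasta(fasta)
    library = RepeatLibrary.from_fasta(library_fa)
    lines_written = 0
    all_elements: list[tuple[str, list[AnnotatedElement]]] = []
    for region_id, seq in sequences.items():
        elements = annotate_region(seq, library, **params)
        all_elements.append((region_id, elements))
        lines_written += len(elements)
    _write_multi_region_gff3(out_gff3, all_elements)
    return lines_written


def _write_multi_region_gff3(path, per_region) -> None:
    chunks = [io.GFF_VERSION_LINE + "\n"]
    for region_id, elements in per_region:
        tmp = Path(str(path) + ".part")
        io.write_elements_gff3(tmp, region_id, elements)
        body = tmp.read_text().splitlines()[1:]
        tmp.unlink()
        if body:
            chunks.append("\n".join(body) + "\n")
    Path(path).write_text("".join(chunks))


def stage_classify(ann_gff3, library_fa, out_tsv, region_id: str = "region",
                   **params) -> pd.DataFrame:
    """classify: elements GFF3 + library -> per-element fate TSV plus a
    per-region fate-count table next to it (``<out>.region.tsv``)."""
    library = RepeatLibrary.from_fasta(library_fa)
    elements = elements_from_gff3(ann_gff3)
    rows, classified = [], []
    for el in elements:
        try:
            cat = classify_element(el, library, **params)
        except NotClassifiableError:
            continue
        classified.append((el, cat))
        rows.append({"element_id": el.element_id, "family": el.family_name,
                     "start": el.interval[0], "end": el.interval[1],
                     "category": cat.value, "mechanism": mechanism_of(cat).value})
    df = pd.DataFrame(rows, columns=["element_id", "family", "start", "end",
                                     "category", "mechanism"])
    df.to_csv(out_tsv, sep="\t", index=False)
    if classified:
        table = fate_count_table(region_id, classified, library)
        region_rows = [{"category": cat.value,
                        "count": table.counts.get(cat, 0),
                        "mechanism": mechanism_of(cat).value}
                       for cat in FateCategory]
        region_df = pd.DataFrame(region_rows)
        region_df.loc[len(region_df)] = {"category": "Tendency",
                                         "count": table.tendency,
                                         "mechanism": ""}
        region_df.to_csv(str(out_tsv) + ".region.tsv", sep="\t", index=False)
    return df


def stage_date(ann_gff3, fasta, out_tsv, rate: float = DEFAULT_RATE) -> pd.DataFrame:
    """date: K2P distance and T = K/2r for every element with both LTRs."""
    sequences = io.read_fasta(fasta)
    seq = "".join(sequences.values()) if len(sequences) > 1 else \
        next(iter(sequences.values()))
    elements = elements_from_gff3(ann_gff3)
    rows = []
    for el in elements:
        ltr5 = el.features_with_role("5'LTR")
        ltr3 = el.features_with_role("3'LTR")
        if not ltr5 or not ltr3:
            continue
        s5, e5 = ltr5[0].interval
        s3, e3 = ltr3[0].interval
        try:
            est = date_element(seq[s5:e5], seq[s3:e3], r=rate)
        except ValueError:
            continue
        rows.append({"element_id": el.element_id, "P": round(est.P, 6),
                     "Q": round(est.Q, 6), "K": round(est.K, 6),
                     "T_years": round(est.T, 1), "sites_used": est.sites_used})
    df = pd.DataFrame(rows, columns=["element_id", "P", "Q", "K", "T_years",
                                     "sites_used"])
    df.to_csv(out_tsv, sep="\t", index=False)
    return df


def stage_summarize(ann_gff3, fasta, out_dir, genes_gff3=None,
                    fates_tsv=None) -> dict:
    """summarize: composition table + region profile TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences = io.read_fasta(fasta)
    region_id, seq = next(iter(sequences.items()))
    elements = elements_from_gff3(ann_gff3)
    intact_ids: set[str] = set()
    if fates_tsv and Path(fates_tsv).exists():
        fdf = pd.read_csv(fates_tsv, sep="\t")
        intact_ids = set(fdf.loc[fdf["category"].isin(
            [FateCategory.INTACT_LTR.value, FateCategory.INTACT_WITHOUT_TSD.value]),
            "element_id"])
    annotations = [TEAnnotation(interval=el.interval, family=el.family_name,
                                class_label=el.class_label,
                                intact=el.element_id in intact_ids)
                   for el in elements]
    table = composition_table(annotations, len(seq), region_id=region_id)
    table.to_frame().to_csv(out_dir / "composition.tsv", sep="\t", index=False)
    n_genes = len(genes_from_gff3(genes_gff3)) if genes_gff3 else 0
    profile = region_profile(table, n_genes)
    label = chromatin_indicator(profile)
    prof_df = pd.DataFrame([{
        "region_id": region_id,
        "region_length": len(seq),
        "n_genes": n_genes,
        "gene_density_kb_per_gene": (None if profile.gene_density_kb is None
                                     else round(profile.gene_density_kb, 2)),
        "gypsy_percent": round(profile.gypsy_percent, 2),
        "copia_percent": round(profile.copia_percent, 2),
        "class1_total_percent": round(table.class1_total_percent, 2),
        "class2_total_percent": round(table.class2_total_percent, 2),
        "chromatin_label": label,
    }])
    prof_df.to_csv(out_dir / "profile.tsv", sep="\t", index=False)
    return {"composition": table, "profile": profile, "label": label}


def stage_scan_movement(fasta, ann_gff3, out_tsv, genes_gff3=None,
                        homology_tsv=None, min_tsd: int = 8,
                        max_gap: int = 2000, window: int = 500,
                        min_copies: int = 4, max_period: int = 10
                        ) -> pd.DataFrame:
    """scan-movement: patterns A, C, D (and E given homology pairs)."""
    sequences = io.read_fasta(fasta)
    region_id, seq = next(iter(sequences.items()))
    elements = elements_from_gff3(ann_gff3)
    tes = [TEAnnotationLite(te_id=el.element_id, interval=el.interval,
                            class_label=el.class_label) for el in elements]
    genes = genes_from_gff3(genes_gff3) if genes_gff3 else []
    arrays = find_tandem_arrays(seq, max_period=max_period,
                                min_copies=min_copies)
    footprints = []
    footprints += scan_tsd_capture(seq, tes, genes, min_tsd=min_tsd,
                                   max_gap=max_gap)
    footprints += scan_helitron_capture(tes, genes)
    footprints += scan_tandem_flank(seq, genes, arrays, window=window)
    if homology_tsv and Path(homology_tsv).exists():
        pairs_df = pd.read_csv(homology_tsv, sep="\t")
        pairs = list(zip(pairs_df.iloc[:, 0], pairs_df.iloc[:, 1]))
        footprints += flag_retrocopy(genes, pairs)
    rows = [{"pattern": fp.pattern, "start": fp.interval[0],
             "end": fp.interval[1], "score": fp.score,
             "evidence": ";".join(f"{k}={v}" for k, v in sorted(fp.evidence.items()))}
            for fp in footprints]
    df = pd.DataFrame(rows, columns=["pattern", "start", "end", "score",
                                     "evidence"])
    df.to_csv(out_tsv, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# End-to-end runner
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"fasta", "library", "genes", "homology", "seed",
               "annotate", "classify", "date", "summarize", "scan"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """annotate -> classify -> date -> summarize -> scan-movement.

    ``config`` keys: fasta, library, optional genes / homology paths,
    optional per-stage parameter dicts (annotate/classify/date/summarize/
    scan) and a seed (recorded in the manifest; the stages themselves are
    deterministic).  Unknown keys are rejected.  Returns the manifest.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("fasta", "library"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
        if not Path(config[key]).exists():
            raise FileNotFoundError(config[key])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = {k: config.get(k) for k in sorted(_KNOWN_KEYS)}
    outputs = {
        "elements": out / "elements.gff3",
        "fates": out / "fates.tsv",
        "ages": out / "ages.tsv",
        "summary_dir": out / "tables",
        "footprints": out / "footprints.tsv",
    }

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    _stage("annotate", stage_annotate, config["fasta"], config["library"],
           outputs["elements"], **config.get("annotate", {}))
    _stage("classify", stage_classify, outputs["elements"], config["library"],
           outputs["fates"], **config.get("classify", {}))
    _stage("date", stage_date, outputs["elements"], config["fasta"],
           outputs["ages"], **config.get("date", {}))
    _stage("summarize", stage_summarize, outputs["elements"], config["fasta"],
           outputs["summary_dir"], genes_gff3=config.get("genes"),
           fates_tsv=outputs["fates"], **config.get("summarize", {}))
    _stage("scan-movement", stage_scan_movement, config["fasta"],
           outputs["elements"], outputs["footprints"],
           genes_gff3=config.get("genes"), homology_tsv=config.get("homology"),
           **config.get("scan", {}))

    manifest = {
        "package": "ltrfate",
        "version": __version__,
        "seed": config.get("seed"),
        "parameters": resolved,
        "outputs": {},
    }
    for name, path in outputs.items():
        if path.is_dir():
            for sub in sorted(path.glob("*.tsv")):
                manifest["outputs"][f"{name}/{sub.name}"] = _sha256(sub)
        elif path.exists():
            manifest["outputs"][name] = _sha256(path)
    manifest["parameter_hash"] = hashlib.sha256(
        json.dumps(resolved, sort_keys=True, default=str).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest
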