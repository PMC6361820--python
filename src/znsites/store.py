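"""Persist a batch build to SQLite and export it.

``build_database`` runs detection over a directory of PDB files, stores
every structure, site, contact and zinc (including the excluded ones, so
the database holds at least some information on every zinc atom), then
clusters the zinc-binding chains at 90% identity and the sites by
fingerprint, flagging best-resolution representatives.  Builds are
deterministic: the same input directory always produces identical tables.

``export_database`` writes the whole store as JSON, the zinc-binding chain
sequences as FASTA, or the summary statistics as CSV tables.
"""

from __future__ import annotations

import csv
import io
import json
import sqlite3
from pathlib import Path

from znsites.analytics import residue_signature
from znsites.detection import BindingSite, DetectionParameters, detect_sites
from znsites.redundancy import cluster_chains, cluster_sites
from znsites.structure import parse_structure

__all__ = ["build_database", "export_database", "SCHEMA"]

SCHEMA = """
CREATE TABLE structures (
    pdb_id TEXT PRIMARY KEY,
    resolution REAL,
    molecule_name TEXT,
    backbone_only INTEGER NOT NULL,
    assembly_id TEXT
);
CREATE TABLE sites (
    id TEXT PRIMARY KEY,
    pdb_id TEXT NOT NULL REFERENCES structures(pdb_id),
    signature TEXT,
    n_metals INTEGER NOT NULL,
    copies INTEGER NOT NULL,
    cluster_id TEXT,
    is_representative INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE zincs (
    pdb_id TEXT NOT NULL REFERENCES structures(pdb_id),
    chain_id TEXT NOT NULL,
    residue_label TEXT NOT NULL,
    site_id TEXT REFERENCES sites(id),
    exclusion_reason TEXT,
    CHECK ((site_id IS NULL) != (exclusion_reason IS NULL))
);
CREATE TABLE metals (
    site_id TEXT NOT NULL REFERENCES sites(id),
    element TEXT NOT NULL,
    chain_id TEXT NOT NULL,
    residue_label TEXT NOT NULL,
    x REAL, y REAL, z REAL
);
CREATE TABLE contacts (
    site_id TEXT NOT NULL REFERENCES sites(id),
    metal_element TEXT NOT NULL,
    atom_name TEXT NOT NULL,
    element TEXT NOT NULL,
    chain_id TEXT NOT NULL,
    residue_label TEXT NOT NULL,
    residue_name TEXT NOT NULL,
    distance REAL NOT NULL
);
CREATE TABLE site_residues (
    site_id TEXT NOT NULL REFERENCES sites(id),
    chain_id TEXT NOT NULL,
    residue_label TEXT NOT NULL,
    residue_name TEXT NOT NULL,
    is_protein INTEGER NOT NULL
);
CREATE TABLE chains (
    pdb_id TEXT NOT NULL REFERENCES structures(pdb_id),
    chain_id TEXT NOT NULL,
    sequence TEXT NOT NULL,
    cluster_id TEXT,
    PRIMARY KEY (pdb_id, chain_id)
);
CREATE TABLE chain_clusters (
    id TEXT PRIMARY KEY,
    representative_pdb TEXT NOT NULL,
    representative_chain TEXT NOT NULL,
    n_members INTEGER NOT NULL
);
CREATE TABLE site_clusters (
    id TEXT PRIMARY KEY,
    representative_site TEXT NOT NULL REFERENCES sites(id),
    n_members INTEGER NOT NULL
);
CREATE TABLE failures (
    filename TEXT NOT NULL,
    error TEXT NOT NULL
);
"""

_TABLES = (
    "structures", "sites", "zincs", "metals", "contacts",
    "site_residues", "chains", "chain_clusters", "site_clusters", "failures",
)


def build_database(
    input_dir: str | Path,
    db_path: str | Path,
    params: DetectionParameters | None = None,
    resolution_filter: float | None = None,
) -> dict:
    """Detect sites in every ``*.pdb`` under ``input_dir`` and persist them.

    Per-file failures are logged into the ``failures`` table and skipped.
    ``resolution_filter`` (Angstrom) drops structures without a resolution
    at least that good.  Returns a summary dict of row counts.
    """
    params = params or DetectionParameters()
    input_dir = Path(input_dir)
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    con.executescript(SCHEMA)

    all_sites: list[tuple[str, BindingSite]] = []
    for path in sorted(input_dir.glob("*.pdb")):
        pdb_id = path.stem
        try:
            model = parse_structure(path.read_text(), pdb_id=pdb_id)
            if resolution_filter is not None and (
                model.resolution is None or model.resolution >= resolution_filter
            ):
                continue
            sites, exclusions = detect_sites(model, params)
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            con.execute("INSERT INTO failures VALUES (?, ?)", (path.name, str(exc)))
            continue
        con.execute(
            "INSERT INTO structures VALUES (?, ?, ?, ?, ?)",
            (pdb_id, model.resolution, model.molecule_name,
             int(model.backbone_only), model.assembly_id),
        )
        for i, site in enumerate(sites, start=1):
            site_id = f"{pdb_id}-{i}"
            all_sites.append((site_id, site))
            signature = residue_signature(site) if site.protein_residues else None
            con.execute(
                "INSERT INTO sites (id, pdb_id, signature, n_metals, copies)"
                " VALUES (?, ?, ?, ?, ?)",
                (site_id, pdb_id, signature, len(site.metals), site.copies),
            )
            for m in site.metals:
                con.execute(
                    "INSERT INTO metals VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (site_id, m.element, m.source_id[0], m.source_id[1],
                     *map(float, m.position)),
                )
                if m.element == "Zn":
                    con.execute(
                        "INSERT INTO zincs VALUES (?, ?, ?, ?, NULL)",
                        (pdb_id, m.source_id[0], m.source_id[1], site_id),
                    )
            for c in site.contacts:
                con.execute(
                    "INSERT INTO contacts VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    (site_id, c.metal.element, c.atom.name, c.atom.element,
                     c.residue.chain_id, c.residue.label, c.residue.name,
                     round(c.distance, 4)),
                )
            for r in site.residues:
                con.execute(
                    "INSERT INTO site_residues VALUES (?, ?, ?, ?, ?)",
                    (site_id, r.chain_id, r.label, r.name, int(r.is_protein)),
                )
        for record in exclusions:
            con.execute(
                "INSERT INTO zincs VALUES (?, ?, ?, NULL, ?)",
                (pdb_id, record.zinc.source_id[0], record.zinc.source_id[1],
                 record.reason.value),
            )

    # chain and site clustering across the whole store
    sequences: dict[tuple[str, str], str] = {}
    for _, site in all_sites:
        for residue in site.protein_residues:
            key = (site.structure.pdb_id, residue.chain_id)
            if key not in sequences:
                sequences[key] = site.structure.chain(residue.chain_id).sequence
    chain_lookup = {}
    if sequences:
        clusters = cluster_chains(sequences)
        chain_lookup = {key: c for c in clusters for key in c.members}
        for c in clusters:
            con.execute(
                "INSERT INTO chain_clusters VALUES (?, ?, ?, ?)",
                (c.id, c.representative[0], c.representative[1], len(c.members)),
            )
        for (pdb_id, chain_id), seq in sorted(sequences.items()):
            con.execute(
                "INSERT INTO chains VALUES (?, ?, ?, ?)",
                (pdb_id, chain_id, seq, chain_lookup[(pdb_id, chain_id)].id),
            )
        site_by_obj = {id(site): sid for sid, site in all_sites}
        for sc in cluster_sites([s for _, s in all_sites], chain_lookup):
            rep_id = site_by_obj[id(sc.representative)]
            con.execute(
                "INSERT INTO site_clusters VALUES (?, ?, ?)",
                (sc.id, rep_id, len(sc.members)),
            )
            for member in sc.members:
                con.execute(
                    "UPDATE sites SET cluster_id = ?, is_representative = ? WHERE id = ?",
                    (sc.id, int(member is sc.representative), site_by_obj[id(member)]),
                )

    con.commit()
    summary = {
        table: con.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
        for table in _TABLES
    }
    con.close()
    return summary


def _dump_csv(rows: list[tuple], header: list[str]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def export_database(db_path: str | Path, fmt: str, out_dir: str | Path) -> list[Path]:
    """Export a built database as ``json``, ``fasta`` or ``csv`` files."""
    valid = ("json", "fasta", "csv")
    if fmt not in valid:
        raise ValueError(f"unknown export format {fmt!r}; valid formats: {', '.join(valid)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    con = sqlite3.connect(db_path)
    con.row_factory = sqlite3.Row
    written: list[Path] = []

    if fmt == "json":
        payload = {
            table: [dict(r) for r in con.execute(f"SELECT * FROM {table}")]
            for table in _TABLES
        }
        path = out_dir / "database.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        written.append(path)

    elif fmt == "fasta":
        lines = []
        for row in con.execute("SELECT pdb_id, chain_id, sequence FROM chains ORDER BY pdb_id, chain_id"):
            lines.append(f">{row['pdb_id']}_{row['chain_id']}")
            seq = row["sequence"]
            lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        path = out_dir / "chains.fasta"
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)

    else:  # csv statistics tables
        exports = {
            "signatures_all.csv": (
                "SELECT signature, SUM(copies) AS count FROM sites"
                " WHERE signature IS NOT NULL GROUP BY signature"
                " ORDER BY count DESC, signature",
                ["signature", "count"],
            ),
            "signatures_unique.csv": (
                "SELECT signature, COUNT(*) AS count FROM sites"
                " WHERE is_representative = 1 AND signature IS NOT NULL"
                " GROUP BY signature ORDER BY count DESC, signature",
                ["signature", "count"],
            ),
            "coordination.csv": (
                "SELECT n AS coordination_mode, COUNT(*) AS count FROM"
                " (SELECT s.id, COUNT(*) AS n FROM sites s JOIN contacts c"
                "  ON c.site_id = s.id JOIN structures st ON st.pdb_id = s.pdb_id"
                "  WHERE s.n_metals = 1 AND st.resolution < 3.0 GROUP BY s.id)"
                " GROUP BY n ORDER BY n",
                ["coordination_mode", "count"],
            ),
            "coactive.csv": (
                "SELECT m.element,"
                " SUM(CASE WHEN m.element = 'Zn' THEN cnt - 1 ELSE cnt END) AS count,"
                " COUNT(*) AS site_count FROM"
                " (SELECT site_id, element, COUNT(*) AS cnt FROM metals"
                "  GROUP BY site_id, element) m"
                " JOIN sites s ON s.id = m.site_id"
                " WHERE s.n_metals > 1 AND NOT (m.element = 'Zn' AND m.cnt = 1)"
                " GROUP BY m.element ORDER BY count DESC, m.element",
                ["element", "count", "site_count"],
            ),
            "distances.csv": (
                "SELECT c.element, c.distance FROM contacts c"
                " JOIN sites s ON s.id = c.site_id"
                " JOIN structures st ON st.pdb_id = s.pdb_id"
                " WHERE s.n_metals = 1 AND st.resolution < 3.0"
                " ORDER BY c.site_id, c.distance",
                ["element", "distance"],
            ),
        }
        for filename, (query, header) in exports.items():
            rows = [tuple(r) for r in con.execute(query)]
            path = out_dir / filename
            path.write_text(_dump_csv(rows, header))
            written.append(path)

    con.close()
    return written
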