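"""Reading and writing the hybrid UNF container.

A UNF file is a JSON document optionally followed by appended external-file
payloads, so the file as a whole is *not* always clean JSON. Each appended
payload is introduced by a marker line

    #INCLUDED_FILE <fileId>;<filename>

followed by the raw payload bytes and a terminating newline. The JSON body
records an MD5 hash for every referenced external file, so embedded content
can be integrity-checked on read.

The JSON boundary is located by string- and escape-aware brace balancing,
never by scanning for the marker, so payloads are fully binary-safe. When a
payload itself happens to contain marker-like lines, the reader backtracks
over candidate boundaries and prefers the split whose MD5 hashes match the
document records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Any

from . import model
from .errors import (
    ContainerError,
    IntegrityError,
    MissingAttachmentError,
    NotIncludedError,
    ReferenceError_,
    UnfError,
)
from .model import ExternalFile, UnfDocument

#: Marker introducing an appended file. Kept in one place so the dialect can
#: be swapped wholesale if another implementation settles on different text.
INCLUDED_FILE_MARKER = "#INCLUDED_FILE"


@dataclass
class Attachment:
    """An external file carried inside the container."""

    fileId: int
    filename: str
    payload: bytes


def md5_hex(payload: bytes) -> str:
    return hashlib.md5(payload).hexdigest()


# ---------------------------------------------------------------------------
# JSON (de)serialization
# ---------------------------------------------------------------------------

def _frame_to_dict(fr: model.NucleotideFrame) -> dict:
    return {
        "backboneCenter": list(fr.backboneCenter),
        "nucleobaseCenter": list(fr.nucleobaseCenter),
        "baseNormal": list(fr.baseNormal),
        "hydrogenFaceDir": list(fr.hydrogenFaceDir),
    }


def doc_to_dict(doc: UnfDocument) -> dict:
    """Serialize a document to the canonical JSON field layout."""
    d: dict[str, Any] = {
        "version": doc.version,
        "lengthUnits": doc.lengthUnits,
        "angularUnits": doc.angularUnits,
        "name": doc.name,
        "author": doc.author,
        "creationDate": doc.creationDate,
        "doi": doc.doi,
        "externalFiles": [
            {"id": f.id, "path": f.path, "type": f.type,
             "isIncluded": f.isIncluded, "hash": f.hash}
            for f in doc.externalFiles
        ],
        "lattices": [
            {
                "id": lat.id, "name": lat.name, "type": lat.type,
                "position": list(lat.position), "orientation": list(lat.orientation),
                "virtualHelices": [
                    {
                        "id": vh.id, "row": vh.row, "col": vh.col,
                        "designNumber": vh.designNumber,
                        "initialAngle": vh.initialAngle,
                        "cells": [
                            {"id": c.id, "index": c.index, "type": c.type,
                             "fiveToThreeNts": list(c.fiveToThreeNts),
                             "threeToFiveNts": list(c.threeToFiveNts)}
                            for c in vh.cells
                        ],
                    }
                    for vh in lat.virtualHelices
                ],
            }
            for lat in doc.lattices
        ],
        "structures": [
            {
                "id": st.id, "name": st.name,
                "naStrands": [
                    {
                        "id": s.id, "name": s.name, "naType": s.naType,
                        "isScaffold": s.isScaffold, "color": s.color,
                        "fivePrimeId": s.fivePrimeId, "threePrimeId": s.threePrimeId,
                        "chainName": s.chainName, "pdbFileId": s.pdbFileId,
                        "nucleotides": [
                            {"id": nt.id, "base": nt.base, "pair": nt.pair,
                             "prev": nt.prev, "next": nt.next,
                             "pdbResidueId": nt.pdbResidueId,
                             "altPositions": [_frame_to_dict(fr) for fr in nt.altPositions]}
                            for nt in s.nucleotides
                        ],
                    }
                    for s in st.naStrands
                ],
                "aaChains": [
                    {
                        "id": ch.id, "chainName": ch.chainName, "color": ch.color,
                        "nTermId": ch.nTermId, "cTermId": ch.cTermId,
                        "pdbFileId": ch.pdbFileId,
                        "aminoAcids": [
                            {"id": aa.id, "code": aa.code, "prev": aa.prev,
                             "next": aa.next, "pdbResidueId": aa.pdbResidueId,
                             "position": list(aa.position)}
                            for aa in ch.aminoAcids
                        ],
                    }
                    for ch in st.aaChains
                ],
            }
            for st in doc.structures
        ],
        "molecules": {
            "ligands": [
                {"id": lig.id, "name": lig.name,
                 "atoms": [{"element": a.element, "name": a.name,
                            "position": list(a.position)} for a in lig.atoms],
                 "bonds": [list(b) for b in lig.bonds]}
                for lig in doc.molecules.ligands
            ],
            "nanostructures": [
                {"id": m.id, "name": m.name, "externalFileId": m.externalFileId,
                 "position": list(m.position), "orientation": list(m.orientation)}
                for m in doc.molecules.nanostructures
            ],
            "others": [
                {"id": m.id, "name": m.name, "externalFileId": m.externalFileId,
                 "position": list(m.position), "orientation": list(m.orientation)}
                for m in doc.molecules.others
            ],
        },
        "groups": [
            {"id": g.id, "name": g.name, "includedObjects": list(g.includedObjects)}
            for g in doc.groups
        ],
        "modifications": [
            {"location": list(m.location), "code": m.code} for m in doc.modifications
        ],
        "connections": [
            {"id": c.id, "includedObjects": list(c.includedObjects),
             "interaction": c.interaction}
            for c in doc.connections
        ],
        "comments": [
            {"id": c.id, "objectId": c.objectId, "content": c.content}
            for c in doc.comments
        ],
        "misc": doc.misc,
    }
    if doc.simulationBox is not None:
        d["simulationBox"] = list(doc.simulationBox)
    return d


def _frame_from_dict(d: dict) -> model.NucleotideFrame:
    return model.NucleotideFrame(
        backboneCenter=tuple(d["backboneCenter"]),
        nucleobaseCenter=tuple(d["nucleobaseCenter"]),
        baseNormal=tuple(d["baseNormal"]),
        hydrogenFaceDir=tuple(d["hydrogenFaceDir"]),
    )


def doc_from_dict(d: dict) -> UnfDocument:
    """Deserialize the canonical JSON layout back into a document."""
    doc = UnfDocument(
        version=d.get("version", model.UNF_VERSION),
        lengthUnits=d.get("lengthUnits", "A"),
        angularUnits=d.get("angularUnits", "deg"),
        name=d.get("name", ""),
        author=d.get("author", ""),
        creationDate=d.get("creationDate", ""),
        doi=d.get("doi", ""),
        misc=d.get("misc", {}),
    )
    if "simulationBox" in d and d["simulationBox"] is not None:
        doc.simulationBox = tuple(d["simulationBox"])
    doc.externalFiles = [
        ExternalFile(id=f["id"], path=f["path"], type=f.get("type", ""),
                     isIncluded=f.get("isIncluded", False), hash=f.get("hash", ""))
        for f in d.get("externalFiles", [])
    ]
    for ld in d.get("lattices", []):
        lat = model.Lattice(
            id=ld["id"], name=ld.get("name", ""), type=ld["type"],
            position=tuple(ld.get("position", (0, 0, 0))),
            orientation=tuple(ld.get("orientation", (0, 0, 0))),
        )
        for vd in ld.get("virtualHelices", []):
            vh = model.VirtualHelix(
                id=vd["id"], row=vd["row"], col=vd["col"],
                designNumber=vd.get("designNumber", model.NONE_ID),
                initialAngle=vd.get("initialAngle", 0.0),
            )
            for cd in vd.get("cells", []):
                vh.cells.append(model.Cell(
                    id=cd["id"], index=cd["index"], type=cd.get("type", "normal"),
                    fiveToThreeNts=list(cd.get("fiveToThreeNts", [])),
                    threeToFiveNts=list(cd.get("threeToFiveNts", [])),
                ))
            lat.virtualHelices.append(vh)
        doc.lattices.append(lat)
    for sd in d.get("structures", []):
        st = model.Structure(id=sd["id"], name=sd.get("name", ""))
        for strand_d in sd.get("naStrands", []):
            s = model.NaStrand(
                id=strand_d["id"], name=strand_d.get("name", ""),
                naType=strand_d.get("naType", "DNA"),
                isScaffold=strand_d.get("isScaffold", False),
                color=strand_d.get("color", "#FFFFFF"),
                fivePrimeId=strand_d.get("fivePrimeId", model.NONE_ID),
                threePrimeId=strand_d.get("threePrimeId", model.NONE_ID),
                chainName=strand_d.get("chainName", ""),
                pdbFileId=strand_d.get("pdbFileId", model.NONE_ID),
            )
            for nd in strand_d.get("nucleotides", []):
                s.nucleotides.append(model.Nucleotide(
                    id=nd["id"], base=nd.get("base", "N"),
                    pair=nd.get("pair", model.NONE_ID),
                    prev=nd.get("prev", model.NONE_ID),
                    next=nd.get("next", model.NONE_ID),
                    pdbResidueId=nd.get("pdbResidueId", model.NONE_ID),
                    altPositions=[_frame_from_dict(fd) for fd in nd.get("altPositions", [])],
                ))
            st.naStrands.append(s)
        for ch_d in sd.get("aaChains", []):
            ch = model.AaChain(
                id=ch_d["id"], chainName=ch_d.get("chainName", ""),
                color=ch_d.get("color", "#FFFFFF"),
                nTermId=ch_d.get("nTermId", model.NONE_ID),
                cTermId=ch_d.get("cTermId", model.NONE_ID),
                pdbFileId=ch_d.get("pdbFileId", model.NONE_ID),
            )
            for ad in ch_d.get("aminoAcids", []):
                ch.aminoAcids.append(model.AminoAcid(
                    id=ad["id"], code=ad.get("code", "X"),
                    prev=ad.get("prev", model.NONE_ID),
                    next=ad.get("next", model.NONE_ID),
                    pdbResidueId=ad.get("pdbResidueId", model.NONE_ID),
                    position=tuple(ad.get("position", (0, 0, 0))),
                ))
            st.aaChains.append(ch)
        doc.structures.append(st)
    mols = d.get("molecules", {})
    for lig_d in mols.get("ligands", []):
        doc.molecules.ligands.append(model.Ligand(
            id=lig_d["id"], name=lig_d.get("name", ""),
            atoms=[model.LigandAtom(element=a["element"], name=a["name"],
                                    position=tuple(a["position"]))
                   for a in lig_d.get("atoms", [])],
            bonds=[tuple(b) for b in lig_d.get("bonds", [])],
        ))
    for key, target in (("nanostructures", doc.molecules.nanostructures),
                        ("others", doc.molecules.others)):
        for md in mols.get(key, []):
            target.append(model.PlacedMolecule(
                id=md["id"], name=md.get("name", ""),
                externalFileId=md.get("externalFileId", model.NONE_ID),
                position=tuple(md.get("position", (0, 0, 0))),
                orientation=tuple(md.get("orientation", (0, 0, 0))),
            ))
    doc.groups = [model.Group(id=g["id"], name=g.get("name", ""),
                              includedObjects=list(g.get("includedObjects", [])))
                  for g in d.get("groups", [])]
    doc.modifications = [model.Modification(location=list(m.get("location", [])),
                                            code=m.get("code", ""))
                         for m in d.get("modifications", [])]
    doc.connections = [model.Connection(id=c["id"],
                                        includedObjects=list(c.get("includedObjects", [])),
                                        interaction=c.get("interaction", ""))
                       for c in d.get("connections", [])]
    doc.comments = [model.Comment(id=c["id"], objectId=c.get("objectId", model.NONE_ID),
                                  content=c.get("content", ""))
                    for c in d.get("comments", [])]
    doc.bump_id_floor()
    return doc


# ---------------------------------------------------------------------------
# container split / read / write
# ---------------------------------------------------------------------------

def split_payload(raw: bytes) -> tuple[str, bytes]:
    """Split a container into its JSON text and the attachment region.

    The boundary is the end of the first complete top-level JSON value,
    found by brace balancing that is aware of strings and escapes (so a
    string value may contain braces or marker-like text). A single leading
    newline is stripped from the attachment region.
    """
    n = len(raw)
    i = 0
    while i < n and raw[i] in b" \t\r\n":
        i += 1
    if i >= n or raw[i] not in b"{[":
        raise ContainerError("container does not begin with a JSON object or array", i)
    depth = 0
    in_string = False
    escaped = False
    end = -1
    for j in range(i, n):
        b = raw[j]
        if in_string:
            if escaped:
                escaped = False
            elif b == 0x5C:  # backslash
                escaped = True
            elif b == 0x22:  # quote
                in_string = False
        else:
            if b == 0x22:
                in_string = True
            elif b in (0x7B, 0x5B):  # { [
                depth += 1
            elif b in (0x7D, 0x5D):  # } ]
                depth -= 1
                if depth == 0:
                    end = j + 1
                    break
                if depth < 0:
                    raise ContainerError("unbalanced JSON in container", j)
    if end < 0:
        raise ContainerError("truncated JSON in container", n)
    json_text = raw[i:end].decode("utf-8")
    rest = raw[end:]
    if rest.startswith(b"\r\n"):
        rest = rest[2:]
    elif rest.startswith(b"\n"):
        rest = rest[1:]
    return json_text, rest


def _marker_positions(region: bytes) -> list[int]:
    """Start offsets of lines beginning with the inclusion marker."""
    token = INCLUDED_FILE_MARKER.encode()
    positions = []
    if region.startswith(token):
        positions.append(0)
    start = 0
    while True:
        k = region.find(b"\n" + token, start)
        if k < 0:
            break
        positions.append(k + 1)
        start = k + 1
    return positions


def _parse_marker_line(region: bytes, pos: int) -> tuple[int, str, int]:
    """Parse the marker line starting at ``pos``; return
    ``(fileId, filename, payload_start)``."""
    nl = region.find(b"\n", pos)
    if nl < 0:
        raise ContainerError("marker line without terminating newline", pos)
    line = region[pos:nl].decode("utf-8", "replace").rstrip("\r")
    body = line[len(INCLUDED_FILE_MARKER):].strip()
    if ";" not in body:
        raise ContainerError(f"malformed marker line {line!r}", pos)
    fid_text, filename = body.split(";", 1)
    try:
        fid = int(fid_text)
    except ValueError:
        raise ContainerError(f"non-integer fileId in marker line {line!r}", pos)
    return fid, filename, nl + 1


def _payload_slice(region: bytes, start: int, boundary: int | None) -> bytes:
    """Payload between ``start`` and a boundary (next marker or region end),
    dropping the terminating newline the writer appends."""
    if boundary is None:
        chunk = region[start:]
    else:
        # boundary points at '#'; the byte before it is the '\n' that both
        # terminates the payload and starts the next marker line
        chunk = region[start:boundary - 1]
    if boundary is None:
        if chunk.endswith(b"\r\n"):
            chunk = chunk[:-2]
        elif chunk.endswith(b"\n"):
            chunk = chunk[:-1]
    elif chunk.endswith(b"\r"):
        chunk = chunk[:-1]
    return chunk


def _parse_attachments(region: bytes, expected: dict[int, str]) -> list[Attachment]:
    """Parse the attachment region.

    ``expected`` maps included fileIds to their recorded MD5 hashes and is
    used to disambiguate payloads containing marker-like lines: among all
    structurally valid splits the one maximizing hash matches wins.
    """
    if not region.strip():
        return []
    positions = _marker_positions(region)
    if not positions or positions[0] != 0:
        raise ContainerError("attachment region does not start with a marker line", 0)

    best: list[Attachment] | None = None
    best_matches = -1

    def search(pos_idx: int, acc: list[Attachment], matches: int):
        nonlocal best, best_matches
        pos = positions[pos_idx]
        fid, filename, payload_start = _parse_marker_line(region, pos)
        later = [p for p in positions if p > pos and p >= payload_start]
        for boundary in later + [None]:
            payload = _payload_slice(region, payload_start, boundary)
            m = matches + (1 if md5_hex(payload) == expected.get(fid) else 0)
            att = Attachment(fileId=fid, filename=filename, payload=payload)
            if boundary is None:
                if m > best_matches:
                    best_matches = m
                    best = acc + [att]
            else:
                search(positions.index(boundary), acc + [att], m)

    search(0, [], 0)
    assert best is not None
    return best


def read_unf(raw: bytes) -> tuple[UnfDocument, list[Attachment]]:
    """Parse a container into a document and its verified attachments.

    Every external file marked ``isIncluded`` must have an attachment whose
    payload MD5 matches the recorded hash; otherwise an
    :class:`IntegrityError` / :class:`MissingAttachmentError` is raised.
    """
    json_text, region = split_payload(raw)
    try:
        d = json.loads(json_text)
    except json.JSONDecodeError as e:
        raise ContainerError(f"invalid JSON body: {e}", e.pos)
    doc = doc_from_dict(d)
    expected = {f.id: f.hash for f in doc.externalFiles if f.isIncluded}
    attachments = _parse_attachments(region, expected)
    by_id = {a.fileId: a for a in attachments}
    for f in doc.externalFiles:
        if not f.isIncluded:
            continue
        att = by_id.get(f.id)
        if att is None:
            raise MissingAttachmentError(
                f"external file {f.id} ({f.path!r}) is marked included but has no attachment")
        actual = md5_hex(att.payload)
        if actual != f.hash:
            raise IntegrityError(
                f"attachment for file {f.id} fails MD5 check: "
                f"recorded {f.hash}, computed {actual}", file_id=f.id)
    for a in attachments:
        if a.fileId not in {f.id for f in doc.externalFiles}:
            raise ReferenceError_(f"attachment references unknown fileId {a.fileId}")
    return doc, attachments


def write_unf(doc: UnfDocument, attachments: list[Attachment] | None = None) -> bytes:
    """Serialize a document (plus attachments) to container bytes.

    The JSON body uses 2-space indentation with keys in schema order. Each
    attachment follows as a marker line, its raw payload, and a newline,
    in ascending fileId order. ``read_unf(write_unf(doc, a)) == (doc, a)``.
    """
    if attachments is None:
        attachments = list(doc._queued_attachments)
    known = {f.id for f in doc.externalFiles}
    for a in attachments:
        if a.fileId not in known:
            raise ReferenceError_(f"attachment for unknown fileId {a.fileId}")
    included = {f.id for f in doc.externalFiles if f.isIncluded}
    missing = included - {a.fileId for a in attachments}
    if missing:
        raise MissingAttachmentError(
            f"no attachment supplied for included file ids {sorted(missing)}")
    out = bytearray(json.dumps(doc_to_dict(doc), indent=2).encode("utf-8"))
    if attachments:
        out += b"\n"
    # each attachment's terminating newline doubles as the line separator
    # before the next marker, keeping payload boundaries byte-exact
    for a in sorted(attachments, key=lambda a: a.fileId):
        out += f"{INCLUDED_FILE_MARKER} {a.fileId};{a.filename}\n".encode("utf-8")
        out += a.payload
        out += b"\n"
    return bytes(out)


def embed_file(doc: UnfDocument, payload: bytes, filename: str,
               type: str = "pdb") -> ExternalFile:
    """Record ``payload`` as an embedded external file.

    A fresh :class:`ExternalFile` (isIncluded, MD5 of the raw bytes) is added
    to the document and the attachment is queued so a subsequent
    :func:`write_unf` without an explicit attachment list will carry it.
    """
    rec = ExternalFile(id=doc.allocate_id(), path=filename, type=type,
                       isIncluded=True, hash=md5_hex(payload))
    doc.externalFiles.append(rec)
    doc._queued_attachments.append(
        Attachment(fileId=rec.id, filename=filename, payload=payload))
    return rec


def extract_file(doc: UnfDocument, attachments: list[Attachment], file_id: int) -> bytes:
    """Return the payload of an included external file, re-verifying MD5."""
    rec = next((f for f in doc.externalFiles if f.id == file_id), None)
    if rec is None:
        raise ReferenceError_(f"no external file with id {file_id}")
    if not rec.isIncluded:
        raise NotIncludedError(
            f"external file {file_id} is not embedded; fetch it from its path {rec.path!r}")
    att = next((a for a in attachments if a.fileId == file_id), None)
    if att is None:
        raise MissingAttachmentError(f"no attachment for included file {file_id}")
    actual = md5_hex(att.payload)
    if actual != rec.hash:
        raise IntegrityError(
            f"attachment for file {file_id} fails MD5 check: "
            f"recorded {rec.hash}, computed {actual}", file_id=file_id)
    return att.payload


def load(path) -> tuple[UnfDocument, list[Attachment]]:
    """Read a UNF container from a filesystem path."""
    with open(path, "rb") as fh:
        return read_unf(fh.read())


def save(path, doc: UnfDocument, attachments: list[Attachment] | None = None) -> None:
    """Write a UNF container to a filesystem path."""
    with open(path, "wb") as fh:
        fh.write(write_unf(doc, attachments))
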