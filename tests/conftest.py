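from __future__ import annotations

import textwrap

import pytest

from plastarch.io import read_tree_newick


def genbank_text(
    seq: str,
    features: list[tuple[str, str, dict[str, str]]],
    accession: str = "TEST0001",
    circular: bool = True,
) -> str:
    """Render a minimal GenBank flat file for fixture use.

    ``features`` is a list of (type, location string, qualifiers).
    """
    topology = "circular" if circular else "linear"
    lines = [
        f"LOCUS       {accession:<16} {len(seq)} bp    DNA     {topology} PLN 01-JAN-2000",
        "DEFINITION  synthetic fixture.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    for ftype, location, quals in features:
        lines.append(f"     {ftype:<15} {location}")
        for key, val in quals.items():
            if val == "":
                lines.append(f'                     /{key}')
            else:
                lines.append(f'                     /{key}="{val}"')
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def quartet_tree():
    return read_tree_newick("((A,B),(C,D));")


@pytest.fixture
def write_genbank(tmp_path):
    def _write(seq, features, accession="TEST0001", circular=True):
        path = tmp_path / f"{accession}.gb"
        path.write_text(genbank_text(seq, features, accession, circular))
        return path

    return _write
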