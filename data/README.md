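# Experimental inputs for the acceptance report

The published target quantities refer to experimental structures and maps
that cannot be redistributed here and cannot be fetched in an offline
environment. `scripts/acceptance.py` computes every target whose input it
finds in this directory and omits the rest.

To populate (requires network):

```sh
curl -o data/1tyq.pdb https://files.rcsb.org/download/1TYQ.pdb
curl -o data/1oel.pdb https://files.rcsb.org/download/1OEL.pdb
curl -o data/emd_1290.map.gz \
  https://files.wwpdb.org/pub/emdb/structures/EMD-1290/map/emd_1290.map.gz
gunzip data/emd_1290.map.gz
```

Expected files: `1tyq.pdb`, `1oel.pdb`, `emd_1290.map` (or `.mrc`).
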