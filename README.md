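# loopgraft

Homology-based completion of missing loops in crystallographic protein
models, with peptide-plane main-chain repair and Ramachandran Z validation.

About 70% of crystallographic protein structures have unmodeled regions —
"loops" in the broad sense of any missing internal stretch. When the same
protein (or a close homolog) has been solved with that region ordered, the
known conformation can be grafted into the incomplete model and checked
against the experimental density, which is far more reliable than building
a loop from conformational sampling alone. `loopgraft` implements that
workflow at desk scale for crystallographers and model-building pipeline
developers:

- **loop transfer** — detect internal gaps from a case-coded construct
  sequence, superpose donor chains on the eight anchor residues flanking
  the gap (quaternion least squares, DEFY label flips, mutation cropping),
  and graft the donor loop plus the two gap-adjacent residues;
- **filter funnel** — clash adjudication against the model and its
  symmetry copies with a fixed atom-importance hierarchy, duplicate removal
  (0.1 Å), restrained real-space regularization against the map, geometry
  RMSZ / omega / cis filters, a Ramachandran Z Grubbs comparison, and a
  density-ratio acceptance (> 0.25) with a final RSCC ≥ 0.60 gate;
- **main-chain repair** (`fixdmc`) — rebuild 1–3 missing backbone atoms
  from the planarity of the peptide unit CAᵢ–Cᵢ–Oᵢ–Nᵢ₊₁–CAᵢ₊₁, add
  terminal OXT atoms when the construct shows the chain is complete, and
  normalize stray occupancies;
- **validation** (`rama-z`) — a structure-level Ramachandran Z score from
  per-class φ/ψ reference distributions (Gly, Pro, pre-Pro, Ile/Val,
  general);
- **synthetic fixtures** — an ideal-geometry structure generator with gap
  placement, noisy/mutated homolog derivation and Gaussian density maps,
  so the entire funnel is testable without any downloads.

## The core quantities

For a gap with anchors superposed at backbone RMSD *r* (candidates require
*r* < 2.0 Å), each surviving candidate is scored by

- RMSZ per restraint class: `Z = (observed − target)/σ` from a standard
  geometry table; loops are rejected when bond or angle RMSZ > 1.2,
  chirality RMSZ > 1.5, or plane/torsion RMSZ > 2.0;
- the density ratio `⟨ρ⟩_loop / ⟨ρ⟩_control`, where the loop mean is the
  tricubically interpolated map value over loop main-chain atoms and the
  control set holds main-chain atoms ordered in every homolog (all
  non-loop main-chain atoms when fewer than 30); acceptance requires
  ratio > 0.25;
- the Ramachandran Z, `Z = Σ(sᵢ − μ_c)/√(Σ σ_c²)` over per-residue
  log-odds *s* against class reference moments (μ_c, σ_c); a candidate
  with Z < −5 is discarded when it is a 2σ negative outlier against the
  other candidates or the donor conformations.

The best remaining candidate by mean loop density is installed, then kept
only if its RSCC against the map is at least 0.60.

## Worked example

```sh
loopgraft make-fixture --seed 3 --out fx
loopgraft build --model fx/target.pdb --seq fx/construct.fasta \
    --homolog fx/homolog0.pdb --homolog fx/homolog1.pdb \
    --homolog fx/homolog2.pdb --map fx/map.ccp4 --out run
```

prints (abbreviated):

```json
{
 "built": 1,
 "rejected": 0,
 "gaps": ["built"],
 "outputs": {"pdb": "run/loopgraft.pdb", "...": "..."}
}
```

meaning the four-residue gap in the synthetic target was rebuilt from a
donor and accepted by every filter; `run/loopgraft_report.json` holds the
per-candidate verdicts (alignment RMSD, RMSZ values, Ramachandran Z,
density ratio ≈ 1.0, RSCC ≈ 0.94 against the map), and the case-coded
FASTA now shows the gap in uppercase. The same library surface is
available from Python (`loopgraft.run_loopwhole`).

Other subcommands: `loopgraft fixdmc --model in.pdb --seq seq.fasta --out
fixed.pdb` (prints counts of rebuilt atoms, OXT additions and occupancy
resets) and `loopgraft rama-z --model in.pdb` (per-residue scores + chain
Z as JSON).

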