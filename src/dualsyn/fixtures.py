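"""Self-contained synthetic inputs with the structure the model assumes.

The generator produces the three tables the pipeline consumes — a drug
table (name, SMILES), a genes × cells TPM expression matrix, and a
replicate-level synergy triplet table — with no downloads:

* drugs are drawn from a curated in-repo list of real small-molecule
  SMILES, padded with generated linear/branched alkanes and alcohols;
* expression is log-normal TPM with four correlated gene blocks
  (within-block correlation 0.7), mimicking co-expression modules;
* synergy scores follow a planted mechanism mirroring the two
  information sources the dual views consume: a shared-substructure
  term (projection of the AND of the two drugs' Morgan fingerprints)
  plus a structure × expression interaction term (cell-block means
  weighted by pair-specific, fingerprint-derived coefficients), plus
  Gaussian noise. Three replicates are emitted per triplet; a
  configurable fraction is corrupted with sign-flipped or high-variance
  replicates to exercise the reliability filter, and ``domain_shift``
  adds a fingerprint-derived pair offset on designated cells to emulate
  a lab/protocol change for fine-tuning experiments.

Everything is driven by one ``FixtureSpec`` and a single seed;
regeneration with the same spec is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import smiles_to_fingerprint, smiles_to_graph

#: curated real small-molecule SMILES (common drugs and reagents)
CURATED_SMILES: list[str] = [
    "CC(=O)Oc1ccccc1C(=O)O",                  # aspirin
    "CC(=O)Nc1ccc(O)cc1",                     # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",             # ibuprofen
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",           # naproxen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",             # caffeine
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",    # diazepam
    "Clc1ccccc1C(c1ccccc1)N1CCNCC1",           # chlorophenyl piperazine scaffold
    "NC(=O)c1ccc[nH]1",                        # pyrrole amide
    "OC(=O)c1ccccc1O",                         # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",                   # sulfanilamide
    "CC(N)Cc1ccccc1",                          # amphetamine
    "CNC(C)Cc1ccccc1",                         # methamphetamine scaffold
    "OCC(O)CO",                                # glycerol
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",              # citric acid
    "NCCc1ccc(O)c(O)c1",                       # dopamine
    "NC(CO)(CO)CO",                            # tris
    "OC(=O)C=Cc1ccccc1",                       # cinnamic acid
    "COc1cc(C=CC(=O)O)ccc1O",                  # ferulic acid
    "Oc1ccc(C=CC(=O)O)cc1",                    # coumaric acid
    "CC(=O)OC1CC2CCC3C(CCC4(C)C3CCC4(O)C#C)C2(C)CC1",  # steroid-like
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",          # estradiol
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",   # warfarin
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",           # imipramine
    "CN(C)CCC=C1c2ccccc2CCc2ccccc21",          # amitriptyline
    "NCCc1c[nH]c2ccccc12",                     # tryptamine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",             # tryptophan
    "NC(Cc1ccccc1)C(=O)O",                     # phenylalanine
    "NC(Cc1ccc(O)cc1)C(=O)O",                  # tyrosine
    "CC(C)CC(N)C(=O)O",                        # leucine
    "NC(CCC(=O)O)C(=O)O",                      # glutamate
    "NC(CS)C(=O)O",                            # cysteine
    "C1CCNCC1",                                # piperidine
    "C1CCNC1",                                 # pyrrolidine
    "c1ccncc1",                                # pyridine
    "c1ccc2[nH]ccc2c1",                        # indole
    "c1ccc2ncccc2c1",                          # quinoline
    "c1ccc2c(c1)ccc1ccccc12",                  # phenanthrene
    "c1ccc(-c2ccccc2)cc1",                     # biphenyl
    "Oc1ccccc1",                               # phenol
    "Nc1ccccc1",                               # aniline
    "OC(=O)c1ccccc1",                          # benzoic acid
    "O=Cc1ccccc1",                             # benzaldehyde
    "CC(=O)c1ccccc1",                          # acetophenone
    "COc1ccccc1",                              # anisole
    "Clc1ccccc1",                              # chlorobenzene
    "Brc1ccccc1",                              # bromobenzene
    "Cc1ccccc1C",                              # xylene
    "Cc1ccc(C)cc1",                            # p-xylene
    "CC(C)c1ccccc1",                           # cumene
    "C=Cc1ccccc1",                             # styrene
    "OCc1ccccc1",                              # benzyl alcohol
    "NCc1ccccc1",                              # benzylamine
    "O=C(O)c1ccc(O)cc1",                       # 4-hydroxybenzoic acid
    "COC(=O)c1ccccc1",                         # methyl benzoate
    "CCOC(=O)c1ccccc1",                        # ethyl benzoate
    "O=C(Nc1ccccc1)c1ccccc1",                  # benzanilide
    "O=S(=O)(O)c1ccccc1",                      # benzenesulfonic acid
    "NS(=O)(=O)c1ccc(N)cc1",                   # sulfonamide scaffold
    "OC1CCCCC1",                               # cyclohexanol
    "O=C1CCCCC1",                              # cyclohexanone
    "C1CCOC1",                                 # THF
    "C1COCCO1",                                # dioxane
    "CN1CCOCC1",                               # N-methylmorpholine
    "O=C(O)CCCCC(=O)O",                        # adipic acid
    "OCCO",                                    # ethylene glycol
    "CC(O)CO",                                 # propylene glycol
    "CCOCC",                                   # diethyl ether
    "CC(C)=O",                                 # acetone
    "CC#N",                                    # acetonitrile
    "CS(C)=O",                                 # DMSO
    "CN(C)C=O",                                # DMF
    "CCN(CC)CC",                               # triethylamine
    "NC(=O)N",                                 # urea
    "NC(=N)N",                                 # guanidine
    "C(=O)(O)C(=O)O",                          # oxalic acid
    "CC(=O)O",                                 # acetic acid
    "OC(=O)CO",                                # glycolic acid
    "CC(O)C(=O)O",                             # lactic acid
    "OCC1OC(O)C(O)C(O)C1O",                    # glucose (pyranose)
    "Nc1ncnc2[nH]cnc12",                       # adenine
    "O=c1cc[nH]c(=O)[nH]1",                    # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",                   # thymine
    "Nc1cc[nH]c(=O)n1",                        # cytosine (tautomer)
    "O=c1[nH]cnc2[nH]ncc12",                   # allopurinol
    "CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2(O)C#C",  # norethindrone-like
    "CCN(CC)C(=O)C1CN(C)C2Cc3c[nH]c4cccc(C2=C1)c34",  # LSD scaffold
    "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",    # morphine
    "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",  # indomethacin
    "CC(C)NCC(O)COc1ccc2ccccc2c1",             # propranolol
    "CC(C)NCC(O)c1ccc(O)c(O)c1",               # isoproterenol
    "CNCC(O)c1ccc(O)c(O)c1",                   # epinephrine
    "OCC(O)C(O)C(O)C(O)CO",                    # sorbitol
    "CCCCCCCCCCCCCCCC(=O)O",                   # palmitic acid
    "CCCCCCCCC=CCCCCCCCC(=O)O",                # oleic acid
    "C1CC2CCC1CC2",                            # bicyclooctane
    "C1CC2(CC1)CCCC2",                         # spiro ring
]


@dataclass(frozen=True)
class FixtureSpec:
    """Generator conditions for one synthetic study."""

    n_drugs: int = 20
    n_cells: int = 30
    n_genes: int = 64
    n_triplets: int = 2000
    n_blocks: int = 4
    block_corr: float = 0.7
    noise_sd: float = 1.0          # per-triplet mechanism noise
    replicate_sd: float = 0.1      # per-replicate measurement noise
    n_replicates: int = 3
    corrupt_fraction: float = 0.05  # sign-flip / high-CV replicate fraction
    signal_scale: float = 15.0     # synergy-score spread (LOEWE-like units)
    w_fingerprint: float = 0.6     # weight of the shared-substructure term
    w_expression: float = 0.4      # weight of the structure x expression term
    domain_shift: float = 0.0      # pair-offset scale on shifted cells (0 = none)
    shift_cells: tuple[str, ...] = ()
    fp_bits: int = 256
    seed: int = 0


def _generated_smiles(n: int, rng: np.random.Generator) -> list[str]:
    """Linear/branched alkanes and alcohols, all trivially valid."""
    out = []
    while len(out) < n:
        length = int(rng.integers(3, 12))
        s = "C" * length
        kind = rng.integers(0, 3)
        if kind == 1:
            s = s + "O"                       # primary alcohol
        elif kind == 2 and length >= 4:
            cut = int(rng.integers(1, length - 2))
            s = "C" * cut + "C(C)" + "C" * (length - cut - 1)  # branch
        if s not in out:
            out.append(s)
    return out


def make_drug_library(n_drugs: int, seed: int = 0) -> pd.DataFrame:
    """Drug table ``drug_name,smiles`` of valid, unique molecules."""
    if n_drugs <= 0:
        raise ValueError("n_drugs must be positive")
    rng = np.random.default_rng(seed)
    pool = list(CURATED_SMILES)
    if n_drugs > len(pool):
        extra = [s for s in _generated_smiles(2 * (n_drugs - len(pool)), rng)
                 if s not in pool]
        pool.extend(extra)
    chosen = [pool[i] for i in rng.permutation(len(pool))[:n_drugs]]
    for s in chosen:  # every shipped SMILES must round-trip the featurizer
        smiles_to_graph(s)
    return pd.DataFrame({
        "drug_name": [f"D{i:03d}" for i in range(n_drugs)],
        "smiles": chosen,
    })


def make_expression(n_cells: int, n_genes: int, seed: int = 0,
                    n_blocks: int = 4, block_corr: float = 0.7) -> pd.DataFrame:
    """Genes × cells TPM matrix with correlated co-expression blocks.

    Log2-scale expression of gene g in cell c is
    ``mu_g + sqrt(rho) * f_{block(g),c} + sqrt(1-rho) * eps`` with
    standard-normal factors, so genes within a block correlate at
    ``rho`` and across blocks at 0; TPM = 2**log2expr (non-negative).
    """
    rng = np.random.default_rng(seed)
    blocks = np.arange(n_genes) % n_blocks
    factors = rng.standard_normal((n_blocks, n_cells))
    eps = rng.standard_normal((n_genes, n_cells))
    mu = rng.normal(4.0, 1.5, size=n_genes)[:, None]
    logexpr = mu + np.sqrt(block_corr) * factors[blocks] \
        + np.sqrt(1.0 - block_corr) * eps
    tpm = np.power(2.0, logexpr)
    return pd.DataFrame(
        tpm,
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"CL{i:03d}" for i in range(n_cells)],
    )


def _block_means(expression: pd.DataFrame, n_blocks: int) -> np.ndarray:
    """Per-cell means of z-scored log2(TPM+1) within each gene block."""
    logged = np.log2(expression.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)
    z = (logged - mean) / np.where(sd == 0, 1.0, sd)
    blocks = np.arange(len(expression)) % n_blocks
    return np.stack([z[blocks == b].mean(axis=0) for b in range(n_blocks)], axis=1)


def make_synergy(drugs: pd.DataFrame, expression: pd.DataFrame,
                 spec: FixtureSpec) -> pd.DataFrame:
    """Replicate-level triplet table with a planted learnable signal.

    The noiseless score of (A, B, cell) is
    ``signal_scale * (w1 * s_fp + w2 * s_expr)`` where ``s_fp`` projects
    the AND of the two fingerprints onto fixed random coefficients and
    ``s_expr`` couples the cell's co-expression block means to
    pair-specific coefficients derived (by a fixed random linear map)
    from the OR of the fingerprints; both terms are standardized over
    the generated set. The score is symmetric in (A, B) because AND/OR
    are commutative. Corrupted triplets receive replicates that the
    reliability filter must reject.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(drugs["drug_name"])
    fps = {n: smiles_to_fingerprint(s, n_bits=spec.fp_bits)
           for n, s in zip(drugs["drug_name"], drugs["smiles"])}
    cells = list(expression.columns)
    blocks = _block_means(expression, spec.n_blocks)  # (n_cells, n_blocks)
    cell_ix = {c: i for i, c in enumerate(cells)}

    beta = rng.normal(size=spec.fp_bits)
    gamma_map = rng.normal(size=(spec.fp_bits, spec.n_blocks)) / np.sqrt(spec.fp_bits)
    shift_beta = rng.normal(size=spec.fp_bits)

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    combos = [(p, c) for p in pairs for c in cells]
    if spec.n_triplets > len(combos):
        raise ValueError(
            f"cannot draw {spec.n_triplets} triplets from {len(combos)} combinations"
        )
    chosen = [combos[i] for i in
              rng.permutation(len(combos))[:spec.n_triplets]]

    s_fp = np.empty(spec.n_triplets)
    s_expr = np.empty(spec.n_triplets)
    s_shift = np.empty(spec.n_triplets)
    for t, ((a, b), cell) in enumerate(chosen):
        fa, fb = fps[a], fps[b]
        both = fa * fb
        either = np.maximum(fa, fb)
        s_fp[t] = both @ beta
        s_expr[t] = blocks[cell_ix[cell]] @ (either @ gamma_map)
        s_shift[t] = either @ shift_beta

    def std(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    score = spec.signal_scale * (
        spec.w_fingerprint * std(s_fp) + spec.w_expression * std(s_expr)
    ) + rng.normal(scale=spec.noise_sd, size=spec.n_triplets)
    if spec.domain_shift > 0 and spec.shift_cells:
        shifted = np.array([c in spec.shift_cells for (_, c) in chosen])
        score = score + shifted * spec.domain_shift * std(s_shift)

    corrupt = rng.random(spec.n_triplets) < spec.corrupt_fraction
    rows = []
    for t, ((a, b), cell) in enumerate(chosen):
        m = score[t]
        if corrupt[t]:
            base = m if abs(m) > 1.0 else (1.0 if m >= 0 else -1.0)
            if rng.random() < 0.5:  # sign conflict
                reps = [base, -base] + [base] * (spec.n_replicates - 2)
            else:                   # same-sign, CV > 0.5
                reps = [0.1 * base, 1.9 * base] + [base] * (spec.n_replicates - 2)
        else:
            reps = list(m + rng.normal(scale=spec.replicate_sd,
                                       size=spec.n_replicates))
        for r, val in enumerate(reps):
            rows.append((a, b, cell, float(val), r))
    return pd.DataFrame(rows,
                        columns=["drug1", "drug2", "cell", "score",
                                 "replicate_id"])


def make_fixture(spec: FixtureSpec):
    """Generate the full input set (drugs, expression, replicate table)."""
    drugs = make_drug_library(spec.n_drugs, seed=spec.seed)
    expression = make_expression(spec.n_cells, spec.n_genes, seed=spec.seed + 1,
                                 n_blocks=spec.n_blocks,
                                 block_corr=spec.block_corr)
    synergy = make_synergy(drugs, expression, spec)
    return drugs, expression, synergy
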