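"""Positional base-frequency bias around SNPs (Bias % profiles).

For a set of strand-folded SNP records of one canonical class and one
compartment, the observed base frequency at each relative position
j in [-50, -1] u [+1, +50] is compared with the compartment-wide background
frequency of that base:

    bias_percent(b, j) = 100 * (f_obs(b, j) - f_bg(b))

Standard deviations come from bootstrap resampling of whole records
(2,000 repeats by default), and class-matched random non-SNP positions give
a null control profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Genome, SnpRecord, ValidationError
from .util import BASES, encode

__all__ = [
    "BiasProfile",
    "background_frequencies",
    "bias_profile",
    "bootstrap_sd",
    "random_position_control",
    "plot_bias_profile",
]


@dataclass
class BiasProfile:
    """Per-position, per-base bias of SNP context versus background.

    Arrays are indexed ``[position, base]`` where position runs over the
    ``rel_positions`` vector (-50..-1, +1..+50; no position 0) and base over
    A, C, G, T.
    """

    canonical_class: str
    compartment: str
    rel_positions: np.ndarray
    f_obs: np.ndarray
    f_bg: np.ndarray  # per base, position independent
    bias_percent: np.ndarray
    n_snps: int
    bootstrap_sd_: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in enumerate(self.rel_positions):
            for k, b in enumerate(BASES):
                rows.append(
                    {
                        "class": self.canonical_class,
                        "compartment": self.compartment,
                        "rel_pos": int(j),
                        "base": b,
                        "f_obs": self.f_obs[i, k],
                        "f_bg": self.f_bg[k],
                        "bias_pct": self.bias_percent[i, k],
                        "sd": np.nan if self.bootstrap_sd_ is None else self.bootstrap_sd_[i, k],
                        "n": self.n_snps,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def background_frequencies(genome: Genome, compartment: str) -> dict[str, float]:
    """Overall A/C/G/T frequencies across one compartment (N excluded)."""
    counts = np.zeros(5, dtype=np.int64)
    for contig, positions in genome.compartment_positions(compartment):
        counts += np.bincount(genome.codes(contig)[positions], minlength=5)
    total = counts[:4].sum()
    if total == 0:
        raise ValidationError(f"compartment {compartment!r} has no annotated positions")
    return {b: counts[i] / total for i, b in enumerate(BASES)}


def _flank_matrix(records: list[SnpRecord]) -> tuple[np.ndarray, int]:
    flank = len(records[0].flank5)
    mat = np.empty((len(records), 2 * flank), dtype=np.uint8)
    for i, rec in enumerate(records):
        mat[i, :flank] = encode(rec.flank5)
        mat[i, flank:] = encode(rec.flank3)
    return mat, flank


def _check_homogeneous(records: list[SnpRecord]) -> tuple[str, str]:
    classes = {r.canonical_class for r in records}
    compartments = {r.compartment for r in records}
    if len(classes) != 1 or len(compartments) != 1:
        raise ValidationError(
            f"records must share one canonical class and compartment, got {classes}/{compartments}"
        )
    return classes.pop(), compartments.pop()


def _one_hot(mat: np.ndarray) -> np.ndarray:
    """(n, positions) base codes -> (n, positions, 4) float32 indicators."""
    out = np.zeros((*mat.shape, 4), dtype=np.float32)
    for k in range(4):
        out[..., k] = mat == k
    return out


def bias_profile(
    records: list[SnpRecord],
    genome: Genome,
    compartment: str | None = None,
    background: dict[str, float] | None = None,
) -> BiasProfile:
    """Bias % profile over the flanking positions of a homogeneous record set."""
    if not records:
        raise ValidationError("no records")
    cls, comp = _check_homogeneous(records)
    if compartment is not None and comp != compartment:
        raise ValidationError(f"records are {comp}, requested {compartment}")
    if background is None:
        background = background_frequencies(genome, comp)
    f_bg = np.array([background[b] for b in BASES])
    mat, flank = _flank_matrix(records)
    counts = np.stack([(mat == k).sum(axis=0) for k in range(4)], axis=1).astype(float)
    f_obs = counts / len(records)
    rel = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
    return BiasProfile(
        canonical_class=cls,
        compartment=comp,
        rel_positions=rel,
        f_obs=f_obs,
        f_bg=f_bg,
        bias_percent=100.0 * (f_obs - f_bg[None, :]),
        n_snps=len(records),
    )


def bootstrap_sd(
    records: list[SnpRecord],
    genome: Genome,
    compartment: str | None = None,
    n_reps: int = 2000,
    seed: int = 0,
    background: dict[str, float] | None = None,
) -> np.ndarray:
    """Bootstrap SD of bias_percent per (position, base) cell.

    Whole records are resampled with replacement, same size, ``n_reps``
    times; the SD of the per-replicate bias is returned.  Since the
    background term is constant, this equals 100x the SD of the resampled
    observed frequencies.  A single record yields SD 0 everywhere.
    """
    if n_reps < 2:
        raise ValidationError("need n_reps >= 2")
    if not records:
        raise ValidationError("no records")
    _check_homogeneous(records)
    n = len(records)
    mat, _ = _flank_matrix(records)
    x = _one_hot(mat).reshape(n, -1)  # (n, positions*4)
    rng = np.random.default_rng(seed)
    # multinomial resampling weights are equivalent to index resampling
    sums = np.zeros(x.shape[1])
    sq_sums = np.zeros(x.shape[1])
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        w = rng.multinomial(n, np.full(n, 1.0 / n), size=k).astype(np.float32)
        f = (w @ x) / n
        sums += f.sum(axis=0)
        sq_sums += (f.astype(np.float64) ** 2).sum(axis=0)
        done += k
    var = sq_sums / n_reps - (sums / n_reps) ** 2
    sd = 100.0 * np.sqrt(np.clip(var, 0.0, None))
    return sd.reshape(-1, 4)


def bias_profile_with_sd(
    records: list[SnpRecord],
    genome: Genome,
    compartment: str | None = None,
    n_reps: int = 2000,
    seed: int = 0,
) -> BiasProfile:
    """Convenience wrapper: profile plus bootstrap SDs in one object."""
    background = background_frequencies(genome, records[0].compartment)
    profile = bias_profile(records, genome, compartment, background=background)
    profile.bootstrap_sd_ = bootstrap_sd(
        records, genome, compartment, n_reps=n_reps, seed=seed, background=background
    )
    return profile


def random_position_control(
    genome: Genome,
    compartment: str,
    bases: set[str],
    n: int,
    seed: int = 0,
    flank: int = 50,
    exclude_positions: set[tuple[str, int]] | None = None,
) -> list[SnpRecord]:
    """Class-matched non-SNP control records.

    Samples ``n`` positions (uniformly, without replacement) whose plus-strand
    base lies in ``bases`` (the two center bases of a canonical class, e.g.
    {'A','G'}), excluding known SNP positions and positions whose flanks are
    truncated or contain N.  Returns pseudo-records usable with
    :func:`bias_profile`; no strand folding is applied, matching the folded
    orientation of the class.
    """
    exclude_positions = exclude_positions or set()
    base_codes = {BASES.index(b) for b in bases}
    canonical = "".join(sorted(bases))
    candidates: list[tuple[str, np.ndarray]] = []
    for contig, positions in genome.compartment_positions(compartment):
        codes = genome.codes(contig)
        ok = np.isin(codes[positions], list(base_codes))
        pos = positions[ok]
        pos = pos[(pos >= flank) & (pos + flank + 1 <= codes.size)]
        candidates.append((contig, pos))
    total = sum(p.size for _, p in candidates)
    if total < n:
        raise ValidationError(f"only {total} eligible positions for control of size {n}")
    rng = np.random.default_rng(seed)
    flat = np.concatenate([p for _, p in candidates])
    owners = np.concatenate([np.full(p.size, i) for i, (_, p) in enumerate(candidates)])
    records: list[SnpRecord] = []
    seen: set[int] = set()
    order = rng.permutation(flat.size)
    for idx in order:
        if len(records) == n:
            break
        contig, _ = candidates[owners[idx]]
        pos = int(flat[idx])
        if (contig, pos) in exclude_positions or idx in seen:
            continue
        seen.add(idx)
        seq = genome.contigs[contig]
        f5 = seq[pos - flank : pos]
        f3 = seq[pos + 1 : pos + 1 + flank]
        if "N" in f5 or "N" in f3:
            continue
        records.append(
            SnpRecord(
                contig=contig,
                pos=pos,
                snp_class=canonical,
                canonical_class=canonical,
                compartment=compartment,
                flank5=f5,
                flank3=f3,
                zygosity_kind="homosite",
                n_minor_strains=0,
            )
        )
    if len(records) < n:
        raise ValidationError(f"could not collect {n} N-free control positions")
    return records


def plot_bias_profile(profile: BiasProfile, path=None, window: int | None = None):
    """Plot bias_percent per base against relative position (optional save)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    mask = np.ones(profile.rel_positions.size, dtype=bool)
    if window is not None:
        mask = np.abs(profile.rel_positions) <= window
    for k, b in enumerate(BASES):
        ax.plot(profile.rel_positions[mask], profile.bias_percent[mask, k], label=b, marker="o", ms=2)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to SNP (bp)")
    ax.set_ylabel("Bias (%)")
    ax.set_title(f"{profile.canonical_class} / {profile.compartment} (n={profile.n_snps})")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
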