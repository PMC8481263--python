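"""Reading, writing and validating campaign spectrum archives.

The deposited archives (``maincampaign.pkl`` etc.) are three-layer nested
python dictionaries: beam energy -> {"proton": int, layer -> arrays},
where the four layers ``Raw``, ``TOF``, ``BGO``, ``All`` correspond to the
consecutive background-suppression steps and each layer holds five
2048-element arrays: ``counts`` (raw histogram), ``_counts`` (Savitzky-
Golay smoothed), ``baseline`` (SNIP estimate), ``bins`` (uncalibrated
pulse-integral bin positions) and ``calibration`` (energies in MeV).

The reader is deliberately tolerant of serialization drift (byte-string
keys, list leaves) because pickles written by older interpreters vary;
validation is strict about the documented structure and names the
offending energy/layer in every error.  Whether the stored ``counts``
are dead-time corrected is not documented in the archive; they are read
as-is.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LAYER_NAMES",
    "ARRAY_NAMES",
    "N_BINS",
    "CAMPAIGN_SIZES",
    "ArchiveValidationError",
    "LayerArrays",
    "SpectrumRecord",
    "CampaignDataset",
    "energy_key",
    "read_campaign_archive",
    "write_campaign_archive",
    "export_portable",
    "layer_retention",
]

LAYER_NAMES = ("Raw", "TOF", "BGO", "All")
#: archive array names in the deposited order
ARRAY_NAMES = ("_counts", "baseline", "bins", "calibration", "counts")
N_BINS = 2048
CAMPAIGN_SIZES = {"main": 23, "reference": 10, "validation": 10}


class ArchiveValidationError(ValueError):
    """Raised when an archive violates the documented nesting/shape."""


def energy_key(energy: float) -> str:
    """Energies are stored as two-decimal string labels ("115.55")."""
    return f"{float(energy):.2f}"


@dataclass
class LayerArrays:
    """The five per-layer spectrum arrays."""

    counts: np.ndarray
    smoothed_counts: np.ndarray
    baseline: np.ndarray
    bins: np.ndarray
    calibration: np.ndarray

    def validate(self, context: str = "") -> None:
        for name, arr in (
            ("counts", self.counts),
            ("_counts", self.smoothed_counts),
            ("baseline", self.baseline),
            ("bins", self.bins),
            ("calibration", self.calibration),
        ):
            arr = np.asarray(arr)
            if arr.ndim != 1 or arr.size != N_BINS:
                raise ArchiveValidationError(
                    f"{context}: array {name!r} has shape {arr.shape}, "
                    f"expected ({N_BINS},)"
                )
        if np.any(np.asarray(self.counts) < 0):
            raise ArchiveValidationError(f"{context}: negative counts")
        cal = np.asarray(self.calibration, dtype=float)
        if np.any(np.diff(cal) <= 0):
            raise ArchiveValidationError(
                f"{context}: calibration is not strictly increasing"
            )


@dataclass
class SpectrumRecord:
    """One beam energy: proton count plus the four suppression layers."""

    beam_energy: float
    protons: int
    layers: dict[str, LayerArrays]
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        ctx = f"energy {energy_key(self.beam_energy)}"
        if not self.protons > 0:
            raise ArchiveValidationError(f"{ctx}: protons must be > 0")
        missing = [name for name in LAYER_NAMES if name not in self.layers]
        if missing:
            raise ArchiveValidationError(f"{ctx}: missing layer(s) {missing}")
        for name in LAYER_NAMES:
            self.layers[name].validate(context=f"{ctx}, layer {name}")


@dataclass
class CampaignDataset:
    """A named campaign: map from two-decimal energy label to record."""

    campaign_name: str
    records: dict[str, SpectrumRecord]

    def validate(self, check_count: bool = True) -> None:
        if not self.records:
            raise ArchiveValidationError("campaign has no records")
        for rec in self.records.values():
            rec.validate()
        expected = CAMPAIGN_SIZES.get(self.campaign_name)
        if check_count and expected is not None and len(self.records) != expected:
            raise ArchiveValidationError(
                f"campaign {self.campaign_name!r} has {len(self.records)} "
                f"records, expected {expected}"
            )

    def energies(self) -> list[float]:
        return sorted(float(k) for k in self.records)

    def record(self, energy: float) -> SpectrumRecord:
        return self.records[energy_key(energy)]


def _as_text(key) -> str:
    return key.decode() if isinstance(key, (bytes, bytearray)) else str(key)


def _normalise_energy_label(key) -> str:
    text = _as_text(key)
    try:
        return energy_key(float(text))
    except ValueError:
        return text


def read_campaign_archive(
    path, campaign_name: str, *, check_count: bool = True
) -> CampaignDataset:
    """Load and validate a pickled campaign archive.

    Byte-string and text keys and list or array leaves are both
    accepted; unknown extra keys are preserved in ``record.extra`` but
    otherwise ignored.
    """
    with open(path, "rb") as fh:
        raw = pickle.load(fh)
    if not isinstance(raw, dict):
        raise ArchiveValidationError(f"{path}: top level is not a dictionary")

    records: dict[str, SpectrumRecord] = {}
    for key, entry in raw.items():
        label = _normalise_energy_label(key)
        try:
            energy = float(label)
        except ValueError:
            raise ArchiveValidationError(f"non-numeric energy key {label!r}")
        if not isinstance(entry, dict):
            raise ArchiveValidationError(f"energy {label}: entry is not a dictionary")
        entry = {_as_text(k): v for k, v in entry.items()}
        protons = entry.pop("proton", entry.pop("protons", None))
        if protons is None:
            raise ArchiveValidationError(f"energy {label}: missing 'proton' entry")
        layers: dict[str, LayerArrays] = {}
        extra: dict = {}
        for name, value in entry.items():
            if name in LAYER_NAMES:
                if not isinstance(value, dict):
                    raise ArchiveValidationError(
                        f"energy {label}, layer {name}: not a dictionary"
                    )
                arrays = {_as_text(k): np.asarray(v, dtype=float) for k, v in value.items()}
                missing = [a for a in ARRAY_NAMES if a not in arrays]
                if missing:
                    raise ArchiveValidationError(
                        f"energy {label}, layer {name}: missing array(s) {missing}"
                    )
                layers[name] = LayerArrays(
                    counts=arrays["counts"],
                    smoothed_counts=arrays["_counts"],
                    baseline=arrays["baseline"],
                    bins=arrays["bins"],
                    calibration=arrays["calibration"],
                )
            else:
                extra[name] = value
        records[label] = SpectrumRecord(
            beam_energy=energy, protons=int(protons), layers=layers, extra=extra
        )

    dataset = CampaignDataset(campaign_name=campaign_name, records=records)
    dataset.validate(check_count=check_count)
    return dataset


def write_campaign_archive(dataset: CampaignDataset, path, *, check_count: bool = True):
    """Serialise a dataset in the deposited nesting; returns the path."""
    dataset.validate(check_count=check_count)
    out: dict = {}
    for label, rec in dataset.records.items():
        entry: dict = {"proton": int(rec.protons)}
        for name in LAYER_NAMES:
            lay = rec.layers[name]
            entry[name] = {
                "_counts": np.asarray(lay.smoothed_counts, dtype=float),
                "baseline": np.asarray(lay.baseline, dtype=float),
                "bins": np.asarray(lay.bins, dtype=float),
                "calibration": np.asarray(lay.calibration, dtype=float),
                "counts": np.asarray(lay.counts, dtype=float),
            }
        out[label] = entry
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(out, fh, protocol=4)
    return path


def export_portable(dataset: CampaignDataset, directory) -> Path:
    """Write one CSV per energy/layer plus a YAML manifest.

    A portable mirror of the pickled archive so non-python consumers can
    read synthetic campaigns; the pickle remains the canonical format.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"campaign": dataset.campaign_name, "records": []}
    for label in sorted(dataset.records, key=float):
        rec = dataset.records[label]
        files = {}
        for name in LAYER_NAMES:
            lay = rec.layers[name]
            frame = pd.DataFrame(
                {
                    "counts": lay.counts,
                    "_counts": lay.smoothed_counts,
                    "baseline": lay.baseline,
                    "bins": lay.bins,
                    "calibration": lay.calibration,
                }
            )
            fname = f"{dataset.campaign_name}_{label}_{name}.csv"
            frame.to_csv(directory / fname, index=False)
            files[name] = fname
        manifest["records"].append(
            {"energy": label, "protons": int(rec.protons), "layers": files}
        )
    manifest_path = directory / f"{dataset.campaign_name}_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def layer_retention(dataset: CampaignDataset) -> pd.DataFrame:
    """Fraction of Raw-layer events surviving each suppression step.

    Returns a tidy table (beam_energy, layer, retained_fraction) with
    retained_fraction(layer) = sum(counts_layer) / sum(counts_Raw);
    Raw is 1 by construction.
    """
    rows = []
    for label in sorted(dataset.records, key=float):
        rec = dataset.records[label]
        raw_total = float(np.sum(rec.layers["Raw"].counts))
        if raw_total <= 0:
            raise ArchiveValidationError(
                f"energy {label}: Raw layer has zero total counts, "
                "retained fractions undefined"
            )
        for name in LAYER_NAMES:
            rows.append(
                {
                    "beam_energy": float(label),
                    "layer": name,
                    "retained_fraction": float(np.sum(rec.layers[name].counts)) / raw_total,
                }
            )
    return pd.DataFrame(rows)
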