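"""Dataset indexing and leakage-free patient-level partitioning."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASSES = ("benign", "malignant")
BENIGN_SUBTYPES = ("adenosis", "fibroadenoma", "phyllodes_tumor", "tubular_adenoma")
MALIGNANT_SUBTYPES = ("ductal_carcinoma", "lobular_carcinoma",
                      "mucinous_carcinoma", "papillary_carcinoma")
SUBTYPES = BENIGN_SUBTYPES + MALIGNANT_SUBTYPES
MAGNIFICATIONS = (40, 100, 200, 400)
MANIFEST_COLUMNS = ["image_path", "patient_id", "class_label", "subtype", "magnification"]
PARTITIONS = ("train", "val", "test")


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    image_path: str
    patient_id: str
    class_label: str
    subtype: str | None = None
    magnification: int | None = None


class DatasetIndex:
    """Validated collection of manifest rows."""

    def __init__(self, records: list[SampleRecord]):
        if not records:
            raise ManifestError("empty dataset index")
        self.records = list(records)
        self._by_patient: dict[str, list[SampleRecord]] = {}
        labels: dict[str, str] = {}
        for r in self.records:
            self._by_patient.setdefault(r.patient_id, []).append(r)
            prev = labels.setdefault(r.patient_id, r.class_label)
            if prev != r.class_label:
                raise ManifestError(
                    f"patient {r.patient_id!r} carries both labels "
                    f"{prev!r} and {r.class_label!r}")
        self.patient_labels = labels

    def __len__(self):
        return len(self.records)

    @property
    def patients(self) -> list[str]:
        return sorted(self._by_patient)

    def patients_with_label(self, label: str) -> list[str]:
        return sorted(p for p, l in self.patient_labels.items() if l == label)

    def records_for(self, patients) -> list[SampleRecord]:
        wanted = set(patients)
        return [r for r in self.records if r.patient_id in wanted]

    def subset(self, patients) -> "DatasetIndex":
        return DatasetIndex(self.records_for(patients))

    def filter_magnification(self, magnification: int) -> "DatasetIndex":
        return DatasetIndex([r for r in self.records if r.magnification == magnification])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=MANIFEST_COLUMNS)


def load_manifest(path: str | Path) -> DatasetIndex:
    """Read and validate a comma-separated manifest."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ManifestError(f"{path}: empty manifest file") from None
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ManifestError(f"{path}: manifest has no rows")
    records = []
    seen_paths: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        label = str(row.class_label).strip().lower()
        if label not in CLASSES:
            raise ManifestError(f"{path}:{i}: unknown class_label {row.class_label!r}")
        ip = str(row.image_path)
        if ip in seen_paths:
            raise ManifestError(
                f"{path}:{i}: duplicate image_path {ip!r} (first at line {seen_paths[ip]})")
        seen_paths[ip] = i
        subtype = None if pd.isna(row.subtype) else str(row.subtype).strip().lower()
        if subtype is not None and subtype not in SUBTYPES:
            raise ManifestError(f"{path}:{i}: unknown subtype {row.subtype!r}")
        mag = None
        if not pd.isna(row.magnification):
            try:
                mag = int(float(row.magnification))
            except ValueError:
                raise ManifestError(
                    f"{path}:{i}: bad magnification {row.magnification!r}") from None
            if mag not in MAGNIFICATIONS:
                raise ManifestError(f"{path}:{i}: unknown magnification {mag}")
        records.append(SampleRecord(ip, str(row.patient_id), label, subtype, mag))
    return DatasetIndex(records)


def write_manifest(index_or_records, path: str | Path) -> None:
    records = index_or_records.records if isinstance(index_or_records, DatasetIndex) \
        else list(index_or_records)
    pd.DataFrame([r.__dict__ for r in records], columns=MANIFEST_COLUMNS).to_csv(
        path, index=False)


@dataclass
class SplitPlan:
    """patient_id -> partition name (or fold label)."""

    assignment: dict[str, str]
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2)
    seed: int = 0

    def patients_in(self, partition: str) -> list[str]:
        return sorted(p for p, a in self.assignment.items() if a == partition)

    @property
    def partitions(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def save(self, out_dir: str | Path, name: str = "split") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = sorted(self.assignment.items())
        pd.DataFrame(rows, columns=["patient_id", "assignment"]).to_csv(
            out_dir / f"{name}.csv", index=False)
        (out_dir / f"{name}.json").write_text(json.dumps(
            {"fractions": list(self.fractions), "seed": self.seed}, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path, name: str = "split") -> "SplitPlan":
        out_dir = Path(out_dir)
        df = pd.read_csv(out_dir / f"{name}.csv", dtype=str)
        meta = json.loads((out_dir / f"{name}.json").read_text())
        return cls(dict(zip(df.patient_id, df.assignment)),
                   tuple(meta["fractions"]), int(meta["seed"]))


def _partition_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Floor each quota; remaining seats go to the largest target fraction.

    Deterministic rounding rule frozen by contract: 82 patients at
    (0.6, 0.2, 0.2) yields (50, 16, 16).
    """
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    order = sorted(range(len(fractions)), key=lambda i: (-fractions[i], i))
    j = 0
    while sum(sizes) < n:
        sizes[order[j % len(order)]] += 1
        j += 1
    return sizes


def patient_stratified_split(index: DatasetIndex,
                             fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                             seed: int = 0) -> SplitPlan:
    """Shuffle patients, stratify by patient-level class, allocate 60/20/20."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(fractions) != len(PARTITIONS):
        raise ValueError("expected three fractions (train, val, test)")
    patients = index.patients
    if len(patients) < len(PARTITIONS):
        raise ValueError(f"need at least {len(PARTITIONS)} patients, got {len(patients)}")
    targets = _partition_sizes(len(patients), fractions)
    remaining = list(targets)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    # per-class largest-remainder allocation constrained by the overall sizes
    for label in CLASSES:
        group = index.patients_with_label(label)
        if not group:
            continue
        rng.shuffle(group)
        quotas = [len(group) * f for f in fractions]
        alloc = [min(int(np.floor(q)), remaining[i]) for i, q in enumerate(quotas)]
        leftover = len(group) - sum(alloc)
        order = sorted(range(len(fractions)),
                       key=lambda i: (-(quotas[i] - np.floor(quotas[i])), i))
        j = 0
        while leftover > 0:
            i = order[j % len(order)]
            if remaining[i] - alloc[i] > 0:
                alloc[i] += 1
                leftover -= 1
            j += 1
        pos = 0
        for i, part in enumerate(PARTITIONS):
            for p in group[pos:pos + alloc[i]]:
                assignment[p] = part
            remaining[i] -= alloc[i]
            pos += alloc[i]
    return SplitPlan(assignment, tuple(fractions), seed)


def kfold_patient_stratified(index: DatasetIndex, k: int = 5,
                             seed: int = 0) -> list[SplitPlan]:
    """k plans; plan i holds out fold i. Folds are patient-disjoint, sizes
    differ by at most one, and each class is dealt round-robin across folds."""
    patients = index.patients
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(patients):
        raise ValueError(f"k={k} exceeds patient count {len(patients)}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    cursor = 0  # global round-robin cursor keeps overall fold sizes within 1
    for label in CLASSES:
        group = index.patients_with_label(label)
        rng.shuffle(group)
        for p in group:
            fold_of[p] = cursor % k
            cursor += 1
    plans = []
    for i in range(k):
        assignment = {p: ("test" if f == i else "train") for p, f in fold_of.items()}
        plan = SplitPlan(assignment, fractions=(1 - 1 / k, 0.0, 1 / k), seed=seed)
        plan.fold = i
        plan.fold_of = dict(fold_of)
        plans.append(plan)
    return plans


def compute_class_weights(index: DatasetIndex) -> dict[str, float]:
    """Inverse-frequency loss weights, image-weighted mean normalized to 1."""
    counts = {c: 0 for c in CLASSES}
    for r in index.records:
        counts[r.class_label] += 1
    absent = [c for c, n in counts.items() if n == 0]
    if absent:
        raise ValueError(f"class(es) {absent} absent from index")
    n = len(index.records)
    k = len(CLASSES)
    return {c: n / (k * counts[c]) for c in CLASSES}


def check_no_leakage(*patient_sets) -> None:
    """Raise if any patient appears in more than one of the given sets."""
    seen: set = set()
    for s in patient_sets:
        overlap = seen & set(s)
        if overlap:
            raise ValueError(f"patient leakage across partitions: {sorted(overlap)}")
        seen |= set(s)


def breakhis_folder_manifest(root: str | Path, out_path: str | Path) -> Path:
    """Best-effort adapter: walk a BreakHis-style directory tree and emit a
    manifest. Expects ``.../<subtype>/SOB_<B|M>_<ST>_<year>-<patient>/<mag>X/*.png``.
    """
    root = Path(root)
    records = []
    for png in sorted(root.rglob("*.png")):
        parts = png.parts
        mag = None
        for part in parts:
            if part.upper().endswith("X") and part[:-1].isdigit():
                mag = int(part[:-1])
        tokens = png.stem.split("_")
        label = None
        patient = None
        for part in (*parts, png.stem):
            for tok in part.split("_"):
                if tok in ("B", "M"):
                    label = "benign" if tok == "B" else "malignant"
        for part in parts:
            if part.startswith("SOB_"):
                patient = part
        if label is None or patient is None:
            continue
        records.append(SampleRecord(str(png), patient, label, None, mag))
    if not records:
        raise ManifestError(f"no BreakHis-style images found under {root}")
    write_manifest(records, out_path)
    return Path(out_path)
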