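import numpy as np
import pytest

from ctviz.phantom import default_spec, generate_phantom
from ctviz.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Small random int16 volume with anisotropic spacing."""
    data = rng.integers(-1000, 2000, size=(9, 7, 11), dtype=np.int16)
    return Volume(data=data, spacing=(0.8, 1.1, 0.625), origin=(1.0, -2.0, 3.0))


@pytest.fixture(scope="session")
def phantom_small():
    """Reduced-size vessel phantom shared across tests (deterministic, seed 7)."""
    spec = default_spec(dims=(40, 40, 80), seed=7)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


def make_dicom_slice(path, *, z, rows=8, cols=6, series_uid="1.2.3.4", instance=1,
                     pixel=None, slope=1.0, intercept=0.0, spacing=(0.9, 0.7),
                     thickness=0.625):
    """Write one synthetic single-frame CT DICOM slice."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = series_uid
    ds.InstanceNumber = instance
    ds.Rows = rows
    ds.Columns = cols
    ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]  # (row=y, col=x)
    ds.SliceThickness = str(thickness)
    ds.ImagePositionPatient = ["0", "0", str(z)]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.RescaleSlope = str(slope)
    ds.RescaleIntercept = str(intercept)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    if pixel is None:
        pixel = np.full((rows, cols), int(z * 10), dtype=np.int16)
    ds.PixelData = np.ascontiguousarray(pixel, dtype=np.int16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
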