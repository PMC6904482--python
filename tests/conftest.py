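import pytest

from cadrepro import Box, Dataset, Detection, Exam, ExamPair, Lesion


def make_pair(patient_id, lesion_boxes, fu_boxes=None, image_size=1024):
    """Build an ExamPair with given initial lesion boxes (followup defaults same)."""
    fu_boxes = fu_boxes if fu_boxes is not None else lesion_boxes
    init = Exam(f"{patient_id}_I", patient_id, "initial", image_size, image_size)
    fu = Exam(f"{patient_id}_F", patient_id, "followup", image_size, image_size)
    init_lesions = tuple(
        Lesion(f"{patient_id}_L{i}", init.exam_id, Box(*b))
        for i, b in enumerate(lesion_boxes)
    )
    fu_lesions = tuple(
        Lesion(f"{patient_id}_L{i}", fu.exam_id, Box(*b))
        for i, b in enumerate(fu_boxes)
    )
    return ExamPair(patient_id, init, fu, init_lesions, fu_lesions)


def det(exam_id, box, conf):
    return Detection(exam_id, Box(*box), conf)


@pytest.fixture
def two_pair_dataset():
    """Two patients, one lesion each; detections hit pair 1 twice, pair 2 once."""
    p1 = make_pair("PA", [(100, 100, 200, 200)])
    p2 = make_pair("PB", [(300, 300, 420, 420)])
    detections = {
        "PA_I": [det("PA_I", (102, 101, 203, 199), 0.9),
                 det("PA_I", (600, 600, 700, 700), 0.3)],
        "PA_F": [det("PA_F", (98, 99, 201, 202), 0.8)],
        "PB_I": [det("PB_I", (305, 301, 418, 425), 0.7)],
        "PB_F": [det("PB_F", (700, 50, 800, 150), 0.4)],
    }
    return Dataset(pairs=[p1, p2], detections=detections)
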