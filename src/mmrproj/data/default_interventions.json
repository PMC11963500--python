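[
  {
    "id": "safe_abortion_services",
    "period": "periconceptual",
    "targets": [
      {"cause": "abortion", "efficacy": 0.85, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "tetanus_toxoid",
    "period": "pregnancy",
    "targets": [
      {"cause": "other_direct", "efficacy": 0.5, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "micronutrient_supplementation",
    "period": "pregnancy",
    "targets": [
      {"cause": "indirect", "efficacy": 0.5, "affected_fraction": 1.0},
      {"cause": "postpartum_hemorrhage", "efficacy": 0.5, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "hypertensive_disorder_case_management",
    "period": "pregnancy",
    "targets": [
      {"cause": "hypertensive_disorders", "efficacy": 0.7, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "clean_birth_environment",
    "period": "childbirth",
    "targets": [
      {"cause": "sepsis", "efficacy": 0.5, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "mgso4_for_eclampsia",
    "period": "childbirth",
    "targets": [
      {"cause": "hypertensive_disorders", "efficacy": 0.6, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "antibiotics_for_prom",
    "period": "childbirth",
    "targets": [
      {"cause": "sepsis", "efficacy": 0.6, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "antibiotics_for_maternal_sepsis",
    "period": "childbirth",
    "targets": [
      {"cause": "sepsis", "efficacy": 0.8, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "assisted_vaginal_delivery",
    "period": "childbirth",
    "targets": [
      {"cause": "intrapartum_hemorrhage", "efficacy": 0.7, "affected_fraction": 1.0},
      {"cause": "other_direct", "efficacy": 0.6, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "uterotonics_for_pph",
    "period": "childbirth",
    "targets": [
      {"cause": "postpartum_hemorrhage", "efficacy": 0.8, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "manual_removal_of_placenta",
    "period": "childbirth",
    "targets": [
      {"cause": "postpartum_hemorrhage", "efficacy": 0.6, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "removal_of_retained_products",
    "period": "childbirth",
    "targets": [
      {"cause": "postpartum_hemorrhage", "efficacy": 0.5, "affected_fraction": 1.0},
      {"cause": "abortion", "efficacy": 0.5, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "cesarean_delivery",
    "period": "childbirth",
    "targets": [
      {"cause": "antepartum_hemorrhage", "efficacy": 0.8, "affected_fraction": 1.0},
      {"cause": "intrapartum_hemorrhage", "efficacy": 0.8, "affected_fraction": 1.0},
      {"cause": "hypertensive_disorders", "efficacy": 0.5, "affected_fraction": 1.0},
      {"cause": "other_direct", "efficacy": 0.6, "affected_fraction": 1.0}
    ]
  },
  {
    "id": "blood_transfusion",
    "period": "childbirth",
    "targets": [
      {"cause": "antepartum_hemorrhage", "efficacy": 0.7, "affected_fraction": 1.0},
      {"cause": "postpartum_hemorrhage", "efficacy": 0.7, "affected_fraction": 1.0}
    ]
  }
]
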