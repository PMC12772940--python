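{
  "$defs": {
    "CovariateRelation": {
      "additionalProperties": false,
      "description": "One multiplicative covariate effect on a PK parameter.\n\nForms (``x`` is the resolved covariate value, ``ref`` the reference):\n\n- ``power``:         ``(x / ref) ** theta``\n- ``proportional``:  ``1 + theta * x`` (for comedication/formulation tags\n  ``x`` is 0/1, so present tag multiplies by ``1 + theta``)\n- ``linear``:        ``1 + theta * (x - ref)``\n- ``exponential``:   ``exp(theta * (x - ref))``",
      "properties": {
        "target_param": {
          "title": "Target Param",
          "type": "string"
        },
        "covariate": {
          "title": "Covariate",
          "type": "string"
        },
        "form": {
          "enum": [
            "power",
            "proportional",
            "linear",
            "exponential"
          ],
          "title": "Form",
          "type": "string"
        },
        "theta": {
          "title": "Theta",
          "type": "number"
        },
        "ref_value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ref Value"
        }
      },
      "required": [
        "target_param",
        "covariate",
        "form",
        "theta"
      ],
      "title": "CovariateRelation",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Declarative population-PK model for one drug and formulation.",
  "properties": {
    "drug_name": {
      "title": "Drug Name",
      "type": "string"
    },
    "formulation": {
      "default": "IR_tablet",
      "enum": [
        "IR_tablet",
        "ER_tablet",
        "solution",
        "suspension",
        "syrup"
      ],
      "title": "Formulation",
      "type": "string"
    },
    "structure": {
      "enum": [
        "one_cpt_oral",
        "one_cpt_bolus",
        "two_cpt_oral"
      ],
      "title": "Structure",
      "type": "string"
    },
    "typical_params": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Typical Params",
      "type": "object"
    },
    "covariates": {
      "items": {
        "$ref": "#/$defs/CovariateRelation"
      },
      "title": "Covariates",
      "type": "array"
    },
    "omega": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Omega",
      "type": "object"
    },
    "omega_corr": {
      "anyOf": [
        {
          "items": {
            "items": {
              "type": "number"
            },
            "type": "array"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Omega Corr"
    },
    "sigma_add": {
      "default": 0.0,
      "title": "Sigma Add",
      "type": "number"
    },
    "sigma_prop": {
      "default": 0.0,
      "title": "Sigma Prop",
      "type": "number"
    },
    "ref_covariates": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Ref Covariates",
      "type": "object"
    }
  },
  "required": [
    "drug_name",
    "structure",
    "typical_params"
  ],
  "title": "PopPKModelSpec",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
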