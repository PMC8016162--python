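{
  "aggregate_report": {
    "$defs": {
      "ReportMeta": {
        "properties": {
          "config_hash": {
            "title": "Config Hash",
            "type": "string"
          },
          "seed": {
            "title": "Seed",
            "type": "integer"
          },
          "version": {
            "title": "Version",
            "type": "string"
          }
        },
        "required": [
          "config_hash",
          "seed",
          "version"
        ],
        "title": "ReportMeta",
        "type": "object"
      }
    },
    "description": "Schema of the aggregate report file.",
    "properties": {
      "conductance": {
        "additionalProperties": {
          "additionalProperties": true,
          "type": "object"
        },
        "title": "Conductance",
        "type": "object"
      },
      "meta": {
        "$ref": "#/$defs/ReportMeta"
      },
      "populations_percent": {
        "additionalProperties": {
          "additionalProperties": {
            "type": "number"
          },
          "type": "object"
        },
        "title": "Populations Percent",
        "type": "object"
      },
      "replicas": {
        "items": {
          "type": "string"
        },
        "title": "Replicas",
        "type": "array"
      },
      "timestamp": {
        "title": "Timestamp",
        "type": "string"
      }
    },
    "required": [
      "populations_percent",
      "conductance",
      "replicas",
      "meta",
      "timestamp"
    ],
    "title": "AggregateReport",
    "type": "object"
  },
  "replica_report": {
    "$defs": {
      "ReportMeta": {
        "properties": {
          "config_hash": {
            "title": "Config Hash",
            "type": "string"
          },
          "seed": {
            "title": "Seed",
            "type": "integer"
          },
          "version": {
            "title": "Version",
            "type": "string"
          }
        },
        "required": [
          "config_hash",
          "seed",
          "version"
        ],
        "title": "ReportMeta",
        "type": "object"
      }
    },
    "description": "Schema of one per-replica report file.",
    "properties": {
      "meta": {
        "$ref": "#/$defs/ReportMeta"
      },
      "replica": {
        "title": "Replica",
        "type": "string"
      },
      "sections": {
        "additionalProperties": true,
        "title": "Sections",
        "type": "object"
      },
      "timestamp": {
        "title": "Timestamp",
        "type": "string"
      }
    },
    "required": [
      "replica",
      "sections",
      "meta",
      "timestamp"
    ],
    "title": "ReplicaReport",
    "type": "object"
  }
}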