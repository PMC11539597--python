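/root/pkg/teststest_simulate.pytest_coexpression.pytest_enrichment.pytest_preprocess.pytest_genescore.pyreference.pyconftest.pytest_acceptance.pytest_fusion.pytest_workflow.py �   ����̅�%�]�����         �   �����7���1y����         �   ����V�'-N�����         �   d���#���E��"����         �   8���v���-}����         �   ���c�[Zr�Rp����         �   �����N/�pM 1����          �   ����"6k� n������                                         �   O���&�J�.����         �   ���C�������         P"�J N'Sy:P"�J N'Sy:��������� �   ��������
      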