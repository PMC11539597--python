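/root/pkg/src/glycofusepreprocess.pygenescore.pysimulate.pyfusion.pycoexpression.py_exceptions.pyworkflow.pyscenarios.py__init__.pyenrichment.py                                �   �����U��`"'����         �   �������-�Qι����         �   |���m53�T)�����         �   Q���0��Gϥܥ����         �   #���7�!�[a�����         �   ����Lُ��-����         �   ����~Z�**�g"����          �   ����CE���� �����         �   t����_^�6E����         cli.py��mp��٥����         �   '�����,�"o�����         _io.py���:�� �%����         WI:}*9Zr-)7/�WI:}*9Zr-)7/������ �   ��������      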